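"""Paired per-donor differences and three-population Z-score normalization.

For each donor pair the protein-by-protein difference
``D = log2(IFN intensity) − log2(CTL intensity)`` is formed over the union
of quantified proteins.  The differences fall into three populations:

* **central** — proteins quantifiable in both conditions (``mode=both``);
* **ifn_only** / **ctl_only** — proteins quantifiable in exactly one
  condition (mode-unique proteins, the outer populations).

Mode-unique differences are the signed log2 intensity of the observed
mode: ``D = +ifn_log2`` for IFN-only, ``D = −ctl_log2`` for CTL-only.
Since detected proteins carry large positive log2 intensities, this places
the two outer populations far on either flank of the central one.

Each donor's central population supplies the mean and SD used to normalize
all three populations of that donor onto a common Z scale (central
population → mean 0, SD 1).  The outer-population Z-scores are not
calibrated probabilities — they simply put presence/absence events onto
the same scale so cross-donor comparison is possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, InsufficientDataError
from .quantitation import ProteinQuant

MODE_BOTH = "both"
MODE_IFN_ONLY = "ifn_only"
MODE_CTL_ONLY = "ctl_only"

#: Consistency constant making the median absolute deviation a normal-
#: consistent scale estimate.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class PairDifference:
    """One protein's paired difference for one donor."""

    accession: str
    donor_id: str
    mode: str
    D: float
    Z: float | None = None
    ifn_log2: float | None = None
    ctl_log2: float | None = None


@dataclass(frozen=True)
class PopulationStats:
    """Central-population location/scale for one donor pair."""

    donor_id: str
    central_mean: float
    central_sd: float
    n_central: int
    n_ifn_only: int
    n_ctl_only: int


def pair_differences(
    ifn: Sequence[ProteinQuant], ctl: Sequence[ProteinQuant]
) -> list[PairDifference]:
    """Form per-donor differences over the union of quantified proteins.

    Proteins quantifiable in neither condition simply do not appear; no
    imputation is performed.

    Raises
    ------
    ConsistencyError
        If the two lists mix donors or carry the wrong conditions.
    """
    donors = {q.donor_id for q in ifn} | {q.donor_id for q in ctl}
    if len(donors) > 1:
        raise ConsistencyError(f"quant lists mix donors: {sorted(donors)}")
    if any(q.condition != "IFN" for q in ifn) or any(q.condition != "CTL" for q in ctl):
        raise ConsistencyError("quant lists carry the wrong condition labels")
    donor_id = donors.pop() if donors else ""

    ifn_by_acc = {q.accession: q for q in ifn}
    ctl_by_acc = {q.accession: q for q in ctl}
    diffs: list[PairDifference] = []
    for acc in sorted(set(ifn_by_acc) | set(ctl_by_acc)):
        qi = ifn_by_acc.get(acc)
        qc = ctl_by_acc.get(acc)
        if qi is not None and qc is not None:
            diffs.append(
                PairDifference(
                    accession=acc,
                    donor_id=donor_id,
                    mode=MODE_BOTH,
                    D=qi.log2_intensity - qc.log2_intensity,
                    ifn_log2=qi.log2_intensity,
                    ctl_log2=qc.log2_intensity,
                )
            )
        elif qi is not None:
            diffs.append(
                PairDifference(
                    accession=acc,
                    donor_id=donor_id,
                    mode=MODE_IFN_ONLY,
                    D=+qi.log2_intensity,
                    ifn_log2=qi.log2_intensity,
                )
            )
        else:
            diffs.append(
                PairDifference(
                    accession=acc,
                    donor_id=donor_id,
                    mode=MODE_CTL_ONLY,
                    D=-qc.log2_intensity,
                    ctl_log2=qc.log2_intensity,
                )
            )
    return diffs


def central_stats(
    diffs: Sequence[PairDifference], robust: bool = False
) -> PopulationStats:
    """Estimate the central (both-mode) population mean and SD.

    By default the sample mean and sample SD (n−1 denominator) are used.
    With ``robust=True`` the median and the normal-consistent MAD
    (median absolute deviation × 1.4826) are used instead, which resists
    inflation by genuinely changed proteins sitting in the tails.

    Raises
    ------
    InsufficientDataError
        If fewer than two both-mode differences exist, or their spread
        is zero.
    """
    central = np.array([d.D for d in diffs if d.mode == MODE_BOTH], dtype=float)
    if central.size < 2:
        raise InsufficientDataError(
            f"need >= 2 both-mode differences, got {central.size}"
        )
    if robust:
        mean = float(np.median(central))
        sd = float(MAD_SCALE * np.median(np.abs(central - mean)))
    else:
        mean = float(np.mean(central))
        sd = float(np.std(central, ddof=1))
    if sd <= 0 or not math.isfinite(sd):
        raise InsufficientDataError("central population has no variance")
    donor_ids = {d.donor_id for d in diffs}
    if len(donor_ids) > 1:
        raise ConsistencyError(f"differences mix donors: {sorted(donor_ids)}")
    return PopulationStats(
        donor_id=donor_ids.pop() if donor_ids else "",
        central_mean=mean,
        central_sd=sd,
        n_central=int(central.size),
        n_ifn_only=sum(d.mode == MODE_IFN_ONLY for d in diffs),
        n_ctl_only=sum(d.mode == MODE_CTL_ONLY for d in diffs),
    )


def normalize(
    diffs: Sequence[PairDifference], stats: PopulationStats
) -> list[PairDifference]:
    """Fill ``Z = (D − central_mean) / central_sd`` for every difference.

    All three populations are standardized by the same central statistics,
    so after normalization (with the default sample estimators) the central
    population has sample mean 0 and sample SD 1 exactly.

    Raises
    ------
    InsufficientDataError
        If ``central_sd`` is not positive.
    ConsistencyError
        If ``stats`` comes from a different donor.
    """
    if stats.central_sd <= 0:
        raise InsufficientDataError("central_sd must be > 0")
    for d in diffs:
        if d.donor_id != stats.donor_id:
            raise ConsistencyError(
                f"stats for donor {stats.donor_id!r} applied to donor {d.donor_id!r}"
            )
    return [
        replace(d, Z=(d.D - stats.central_mean) / stats.central_sd) for d in diffs
    ]
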