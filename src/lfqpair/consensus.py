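"""Cross-donor consensus differential calls and report-row formatting.

A protein qualifies in a donor when its normalized difference reaches
|Z| ≥ 2 (inclusive by default — the headline "≥ |2SD|" criterion).  A
protein is called differentially expressed when it qualifies in the same
direction in at least 3 of the 5 donor pairs; donors with opposite or
non-significant behaviour do not veto the call (no-veto counting).

Mode-unique observations (protein detected in only one condition of a
pair) qualify through the same Z threshold on the outer-population scale;
a configurable alternative treats any quantifiable mode-unique observation
as qualifying.

Display tokens mirror the published reporting convention: a fold value for
proteins seen in both conditions, ``IFN`` / ``CTL`` for proteins detected
only in the treated / untreated sample, and ``–`` for proteins not
detected in that donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .differential import MODE_BOTH, MODE_CTL_ONLY, MODE_IFN_ONLY, PairDifference
from .errors import ConflictError, ConsistencyError

Z_THRESHOLD = 2.0
MIN_PAIRS = 3

DIR_INCREASED = "increased"
DIR_DECREASED = "decreased"
DIR_NONE = "none"

#: Token for "not detected in this donor sample" (en dash, as printed).
ABSENT_TOKEN = "–"

MODE_UNIQUE_Z = "z_threshold"
MODE_UNIQUE_ALWAYS = "always"


@dataclass(frozen=True)
class ConsensusCall:
    """A protein's cross-donor differential verdict."""

    accession: str
    direction: str
    n_qualifying: int
    per_donor_display: tuple[str, ...]


def qualify_pair(
    diff: PairDifference,
    z_threshold: float = Z_THRESHOLD,
    inclusive: bool = True,
    mode_unique_rule: str = MODE_UNIQUE_Z,
) -> str:
    """Classify one donor's difference as ``"up"``, ``"down"`` or ``"none"``.

    Both-mode differences qualify on the Z threshold (inclusive by
    default).  Mode-unique differences qualify in the direction of the
    observed mode, gated by the same |Z| threshold under the default rule,
    or unconditionally under ``mode_unique_rule="always"``.
    """
    if mode_unique_rule not in (MODE_UNIQUE_Z, MODE_UNIQUE_ALWAYS):
        raise ValueError(f"unknown mode_unique_rule {mode_unique_rule!r}")
    if diff.mode == MODE_IFN_ONLY and mode_unique_rule == MODE_UNIQUE_ALWAYS:
        return "up"
    if diff.mode == MODE_CTL_ONLY and mode_unique_rule == MODE_UNIQUE_ALWAYS:
        return "down"
    if diff.Z is None:
        raise ConsistencyError(f"{diff.accession}: Z not computed before qualification")
    up = diff.Z >= z_threshold if inclusive else diff.Z > z_threshold
    down = diff.Z <= -z_threshold if inclusive else diff.Z < -z_threshold
    if diff.mode == MODE_IFN_ONLY:
        return "up" if up else "none"
    if diff.mode == MODE_CTL_ONLY:
        return "down" if down else "none"
    if up:
        return "up"
    if down:
        return "down"
    return "none"


def fold_display(diff: PairDifference | None, direction: str = DIR_INCREASED) -> str:
    """Format one donor's evidence as a report token.

    Both-mode differences are shown as fold change rounded to one decimal:
    ``2**D`` in increased-direction tables, ``2**(−D)`` (fold decrease) in
    decreased-direction tables.  Mode-unique observations display as
    ``IFN`` or ``CTL``; a protein absent from the donor displays as ``–``.
    """
    if diff is None:
        return ABSENT_TOKEN
    if diff.mode == MODE_IFN_ONLY:
        return "IFN"
    if diff.mode == MODE_CTL_ONLY:
        return "CTL"
    d = -diff.D if direction == DIR_DECREASED else diff.D
    return f"{2.0 ** d:.1f}"


def consensus_call(
    diffs: Sequence[PairDifference],
    donor_order: Sequence[str],
    z_threshold: float = Z_THRESHOLD,
    min_pairs: int = MIN_PAIRS,
    inclusive: bool = True,
    mode_unique_rule: str = MODE_UNIQUE_Z,
) -> ConsensusCall:
    """Combine one accession's per-donor differences into a consensus call.

    ``direction`` is ``increased`` (``decreased``) iff at least
    ``min_pairs`` donors qualify up (down); opposite-direction or
    non-significant donors never veto.  Display tokens follow
    ``donor_order`` (one per donor, ``–`` where the protein was absent).

    Raises
    ------
    ConsistencyError
        On two differences for one donor, or an unknown donor.
    ConflictError
        If both directions reach ``min_pairs`` (impossible when
        ``min_pairs > len(donor_order) / 2``).
    """
    accessions = {d.accession for d in diffs}
    if len(accessions) > 1:
        raise ConsistencyError(f"differences mix accessions: {sorted(accessions)}")
    accession = accessions.pop() if accessions else ""

    by_donor: dict[str, PairDifference] = {}
    for d in diffs:
        if d.donor_id in by_donor:
            raise ConsistencyError(f"{accession}: two differences for donor {d.donor_id}")
        if d.donor_id not in donor_order:
            raise ConsistencyError(f"{accession}: unknown donor {d.donor_id!r}")
        by_donor[d.donor_id] = d

    n_up = n_down = 0
    for d in by_donor.values():
        q = qualify_pair(d, z_threshold, inclusive, mode_unique_rule)
        if q == "up":
            n_up += 1
        elif q == "down":
            n_down += 1

    if n_up >= min_pairs and n_down >= min_pairs:
        raise ConflictError(f"{accession}: both directions reach {min_pairs} donors")
    if n_up >= min_pairs:
        direction, n_qualifying = DIR_INCREASED, n_up
    elif n_down >= min_pairs:
        direction, n_qualifying = DIR_DECREASED, n_down
    else:
        direction, n_qualifying = DIR_NONE, max(n_up, n_down)

    display_dir = direction if direction != DIR_NONE else DIR_INCREASED
    display = tuple(fold_display(by_donor.get(donor), display_dir) for donor in donor_order)
    return ConsensusCall(
        accession=accession,
        direction=direction,
        n_qualifying=n_qualifying,
        per_donor_display=display,
    )


def call_all(
    per_donor_diffs: Mapping[str, Sequence[PairDifference]],
    donor_order: Sequence[str],
    z_threshold: float = Z_THRESHOLD,
    min_pairs: int = MIN_PAIRS,
    inclusive: bool = True,
    mode_unique_rule: str = MODE_UNIQUE_Z,
) -> list[ConsensusCall]:
    """Consensus calls for every accession seen in any donor's differences.

    ``per_donor_diffs`` maps donor id → that donor's (normalized)
    difference list.  Returns accession-sorted calls; the result is
    invariant under donor reordering of the input mapping.
    """
    by_accession: dict[str, list[PairDifference]] = {}
    for donor in donor_order:
        for d in per_donor_diffs.get(donor, []):
            by_accession.setdefault(d.accession, []).append(d)
    return [
        consensus_call(
            by_accession[acc], donor_order, z_threshold, min_pairs, inclusive,
            mode_unique_rule,
        )
        for acc in sorted(by_accession)
    ]
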