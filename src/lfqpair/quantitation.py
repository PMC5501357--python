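"""Per-run protein quantitation from summed fragment intensities.

A protein's label-free expression value in a run is the sum of MS/MS
fragment intensities over the confident PSMs of its unique peptides,
mapped onto a log2 scale.  Natural intensities are summed first, then
logged.  Shared-peptide intensity is excluded to avoid double-counting the
same signal under several accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateIntensityError
from .identification import (
    MIN_UNIQUE_PEPTIDES,
    PEPTIDE_LOG_E_MAX,
    PROTEIN_LOG_E_MAX,
    ProteinEvidence,
    assign_uniqueness,
    confident_unique_peptides,
    filter_confident,
    quantifiable,
)
from .psm_io import RunTable


@dataclass(frozen=True)
class ProteinQuant:
    """A protein's log2 expression value in one run."""

    accession: str
    donor_id: str
    condition: str
    log2_intensity: float
    n_distinct_peptides: int
    n_psms: int


def protein_log2_intensity(
    evidence: ProteinEvidence, pep_log_e_max: float = PEPTIDE_LOG_E_MAX
) -> ProteinQuant:
    """Roll one protein's confident unique-peptide PSMs up to a log2 value.

    Only PSMs of unique peptides with ``peptide_log_e`` at or below the
    cut-off contribute to the sum.

    Raises
    ------
    DegenerateIntensityError
        If the contributing intensity sum is not positive.
    """
    confident = confident_unique_peptides(evidence, pep_log_e_max)
    contributing = [
        p
        for p in evidence.psms
        if p.peptide_seq in confident and p.peptide_log_e <= pep_log_e_max
    ]
    total = math.fsum(p.fragment_intensity for p in contributing)
    if total <= 0:
        raise DegenerateIntensityError(
            f"{evidence.accession}: non-positive summed fragment intensity ({total})"
        )
    first = contributing[0]
    return ProteinQuant(
        accession=evidence.accession,
        donor_id=first.donor_id,
        condition=first.condition,
        log2_intensity=math.log2(total),
        n_distinct_peptides=len(confident),
        n_psms=len(contributing),
    )


def quantify_run(
    run: RunTable,
    pep_log_e_max: float = PEPTIDE_LOG_E_MAX,
    prot_log_e_max: float = PROTEIN_LOG_E_MAX,
    min_unique_peptides: int = MIN_UNIQUE_PEPTIDES,
    protein_log_e: dict[str, float] | None = None,
) -> list[ProteinQuant]:
    """Quantify every confidently identified, quantifiable protein of a run.

    Returns one :class:`ProteinQuant` per protein passing both the
    confident-identification and the quantifiability filters, in
    accession-sorted order.  Proteins whose contributing intensity sum is
    degenerate (≤ 0) are dropped.  An empty run yields an empty list.
    """
    evidence = assign_uniqueness(run.records, protein_log_e)
    quants: list[ProteinQuant] = []
    for acc in sorted(evidence):
        ev = evidence[acc]
        if not filter_confident(ev, pep_log_e_max, prot_log_e_max, min_unique_peptides):
            continue
        if not quantifiable(ev, pep_log_e_max, min_unique_peptides):
            continue
        try:
            quants.append(protein_log2_intensity(ev, pep_log_e_max))
        except DegenerateIntensityError:
            continue
    return quants
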