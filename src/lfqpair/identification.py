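"""Confident-identification and quantifiability filters.

A protein is confidently identified in a run when at least two distinct
unique (proteotypic) peptides support it, each with a peptide expectation
score of log(e) ≤ −1.5, and — when a protein-level score is available — a
protein log(e) ≤ −3.  "Distinct" and "non-redundant" are synonyms here:
distinct stripped peptide sequences.

Uniqueness is evaluated per run against the accessions appearing in that
run's PSM table: a peptide is unique iff the union of accessions over all
its PSMs within the run is a single accession.  Shared peptides contribute
PSMs to every listed protein but never to a protein's unique-peptide set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .psm_io import PsmRecord

#: Operative defaults (the quantitative-analysis thresholds, inclusive).
PEPTIDE_LOG_E_MAX = -1.5
PROTEIN_LOG_E_MAX = -3.0
MIN_UNIQUE_PEPTIDES = 2


@dataclass
class ProteinEvidence:
    """All PSM evidence for one protein within one run."""

    accession: str
    psms: list[PsmRecord] = field(default_factory=list)
    distinct_unique_peptides: frozenset[str] = frozenset()
    protein_log_e: float | None = None


def assign_uniqueness(
    records: Iterable[PsmRecord],
    protein_log_e: Mapping[str, float] | None = None,
) -> dict[str, ProteinEvidence]:
    """Group PSMs by protein and determine each protein's unique peptides.

    Parameters
    ----------
    records
        All PSMs of one run (fraction-merged).
    protein_log_e
        Optional map of accession to protein-level log expectation score.
        When absent for a protein, the protein-level filter clause is
        vacuously satisfied.

    Returns
    -------
    dict
        Accession → :class:`ProteinEvidence`.  Every PSM appears under every
        accession it lists; ``distinct_unique_peptides`` holds the peptide
        sequences whose accession union (over the whole run) is exactly
        this protein.
    """
    protein_log_e = protein_log_e or {}
    peptide_accessions: dict[str, set[str]] = {}
    by_accession: dict[str, list[PsmRecord]] = {}
    for rec in records:
        peptide_accessions.setdefault(rec.peptide_seq, set()).update(rec.protein_accessions)
        for acc in rec.protein_accessions:
            by_accession.setdefault(acc, []).append(rec)

    evidence: dict[str, ProteinEvidence] = {}
    for acc, psms in by_accession.items():
        unique = frozenset(
            seq
            for seq in {p.peptide_seq for p in psms}
            if peptide_accessions[seq] == {acc}
        )
        evidence[acc] = ProteinEvidence(
            accession=acc,
            psms=psms,
            distinct_unique_peptides=unique,
            protein_log_e=protein_log_e.get(acc),
        )
    return evidence


def confident_unique_peptides(
    evidence: ProteinEvidence, pep_log_e_max: float = PEPTIDE_LOG_E_MAX
) -> frozenset[str]:
    """Unique peptides with at least one PSM at or below the log(e) cut-off."""
    return frozenset(
        seq
        for seq in evidence.distinct_unique_peptides
        if any(
            p.peptide_seq == seq and p.peptide_log_e <= pep_log_e_max
            for p in evidence.psms
        )
    )


def quantifiable(
    evidence: ProteinEvidence,
    pep_log_e_max: float = PEPTIDE_LOG_E_MAX,
    min_unique_peptides: int = MIN_UNIQUE_PEPTIDES,
) -> bool:
    """True iff enough distinct unique peptides have confident PSMs.

    Peptide sequences — not spectra — are counted: one peptide with many
    PSMs still counts once.
    """
    return len(confident_unique_peptides(evidence, pep_log_e_max)) >= min_unique_peptides


def filter_confident(
    evidence: ProteinEvidence,
    pep_log_e_max: float = PEPTIDE_LOG_E_MAX,
    prot_log_e_max: float = PROTEIN_LOG_E_MAX,
    min_unique_peptides: int = MIN_UNIQUE_PEPTIDES,
) -> bool:
    """Apply the confident-identification filter (thresholds inclusive).

    True iff at least ``min_unique_peptides`` distinct unique peptides each
    have a PSM with ``peptide_log_e`` ≤ ``pep_log_e_max``, and the
    protein-level score (when present) is ≤ ``prot_log_e_max``.
    """
    if not quantifiable(evidence, pep_log_e_max, min_unique_peptides):
        return False
    if evidence.protein_log_e is not None and evidence.protein_log_e > prot_log_e_max:
        return False
    return True
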