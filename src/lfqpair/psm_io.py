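"""Reading, validation and writing of PSM evidence tables.

The canonical input is a tab-separated table with one row per
peptide-spectrum match (PSM), i.e. one assignment of an MS/MS spectrum to a
peptide sequence together with its provenance (donor, condition, first
dimension fraction) and evidence (base-10 log of the search-engine
expectation value, summed MS/MS fragment intensity).  The pipeline starts
from tabulated search output; raw spectra and search-engine XML are out of
scope.

Expectation scores are stored as base-10 log values (``log(e)``); raw
expectation values are never stored.  Fraction files are evidence
partitions only: :func:`merge_fractions` concatenates them with no
spectrum-level de-duplication.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConsistencyError, FormatError, ParseError, ValidationError

CONDITIONS = ("CTL", "IFN")

#: Column order of the canonical PSM TSV.
PSM_COLUMNS = (
    "donor_id",
    "condition",
    "fraction",
    "peptide_seq",
    "charge",
    "protein_accessions",
    "peptide_log_e",
    "fragment_intensity",
)

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    Parameters
    ----------
    donor_id : str
        Label of the donor the sample came from.
    condition : str
        ``"CTL"`` (untreated) or ``"IFN"`` (IFN-γ treated).
    fraction : int
        First-dimension fraction 1..21, or 0 for pre-merged tables.
    peptide_seq : str
        Stripped (modification-free) uppercase peptide sequence.
    charge : int
        Precursor charge state (informational; 2..4 in the acquisition).
    protein_accessions : tuple of str
        Accessions of every protein this peptide maps to (non-empty).
    peptide_log_e : float
        Base-10 log of the expectation value; ≤ 0 for confident matches.
    fragment_intensity : float
        Sum of MS/MS fragment intensities for this match (≥ 0).
    """

    donor_id: str
    condition: str
    fraction: int
    peptide_seq: str
    charge: int
    protein_accessions: tuple[str, ...]
    peptide_log_e: float
    fragment_intensity: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not _PEPTIDE_RE.match(self.peptide_seq):
            raise ValidationError(
                f"peptide_seq {self.peptide_seq!r} is not a plain amino-acid string"
            )
        if not self.protein_accessions:
            raise ValidationError("protein_accessions must be non-empty")
        if any(not a for a in self.protein_accessions):
            raise ValidationError("protein_accessions contains an empty accession")
        if self.fragment_intensity < 0:
            raise ValidationError(
                f"fragment_intensity must be >= 0, got {self.fragment_intensity}"
            )
        if self.fraction < 0:
            raise ValidationError(f"fraction must be >= 0, got {self.fraction}")


@dataclass
class RunTable:
    """All fraction-merged PSM evidence for one (donor, condition) run."""

    donor_id: str
    condition: str
    records: list[PsmRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.donor_id != self.donor_id or rec.condition != self.condition:
                raise ConsistencyError(
                    f"record ({rec.donor_id}, {rec.condition}) does not belong to "
                    f"run ({self.donor_id}, {self.condition})"
                )

    def __len__(self) -> int:
        return len(self.records)


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read a tab-separated PSM table into a list of records, in file order.

    The first line must be a header naming all :data:`PSM_COLUMNS` (extra
    columns are ignored).  Accession lists are semicolon-separated.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    ParseError
        If a numeric field cannot be parsed; the message cites the line.
    ValidationError
        If a row violates a record invariant (e.g. empty accession list).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: file is empty (no header)") from None
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}

        records: list[PsmRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise ParseError(f"{path}, line {lineno}: expected {len(header)} fields, got {len(row)}")

            def _num(col: str, cast):
                raw = row[idx[col]]
                try:
                    return cast(raw)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: cannot parse {col}={raw!r}"
                    ) from None

            accessions = tuple(a for a in row[idx["protein_accessions"]].split(";") if a)
            if not accessions:
                raise ValidationError(f"{path}, line {lineno}: empty protein accession list")
            try:
                rec = PsmRecord(
                    donor_id=row[idx["donor_id"]],
                    condition=row[idx["condition"]],
                    fraction=_num("fraction", int),
                    peptide_seq=row[idx["peptide_seq"]],
                    charge=_num("charge", int),
                    protein_accessions=accessions,
                    peptide_log_e=_num("peptide_log_e", float),
                    fragment_intensity=_num("fragment_intensity", float),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
            records.append(rec)
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    """Write records as the canonical PSM TSV (UTF-8, Unix newlines)."""
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.donor_id,
                    rec.condition,
                    rec.fraction,
                    rec.peptide_seq,
                    rec.charge,
                    ";".join(rec.protein_accessions),
                    repr(rec.peptide_log_e),
                    repr(rec.fragment_intensity),
                ]
            )


def merge_fractions(
    tables: Sequence[Sequence[PsmRecord]], donor_id: str, condition: str
) -> RunTable:
    """Concatenate per-fraction PSM lists into one run.

    Each PSM is independent evidence, so no de-duplication is performed:
    the output record count is the sum of the input counts and the total
    fragment intensity is conserved.

    Raises
    ------
    ConsistencyError
        If any record disagrees with ``donor_id`` or ``condition``.
    """
    merged: list[PsmRecord] = []
    for table in tables:
        for rec in table:
            if rec.donor_id != donor_id or rec.condition != condition:
                raise ConsistencyError(
                    f"record ({rec.donor_id}, {rec.condition}) does not match "
                    f"run ({donor_id}, {condition})"
                )
            merged.append(rec)
    return RunTable(donor_id=donor_id, condition=condition, records=merged)
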