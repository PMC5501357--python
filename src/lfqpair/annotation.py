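"""Membrane/secreted classification and interferon-responsiveness flags.

Called proteins are classified from a local annotation table of
transmembrane-region (TM) and signal-peptide (SP) status:

* **membrane** — has a transmembrane region (regardless of SP);
* **secreted** — no transmembrane region but a signal peptide;
* **other** — neither;
* **unannotated** — accession absent from the annotation table.

Transcript-level interferon responsiveness is flagged from a local table
of maximum absolute transcript fold changes under IFN-γ treatment: a
protein is *responsive* iff its reported absolute fold change is at least
twofold (inclusive).  Both tables are consumed from local TSVs, never
fetched live — reproducibility over liveness.  Curation of the transcript
table (species, tissue restrictions) happens upstream of this package.

A transcription of the published membrane/secreted annotation set ships
with the package (``lfqpair/data/membrane_secreted_annotations.tsv``)
and can be loaded with :func:`load_packaged_membrane_table`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consensus import ConsensusCall
from .errors import FormatError, ParseError, ValidationError

CATEGORY_MEMBRANE = "membrane"
CATEGORY_SECRETED = "secreted"
CATEGORY_OTHER = "other"
CATEGORY_UNANNOTATED = "unannotated"

RESPONSIVE = "responsive"
NOT_REPORTED = "not_reported"

MIN_TRANSCRIPT_FOLD = 2.0


@dataclass(frozen=True)
class AnnotationRecord:
    """TM/SP status of one protein."""

    accession: str
    gene: str
    has_tm: bool
    has_sp: bool


@dataclass(frozen=True)
class TranscriptResponse:
    """Largest absolute transcript fold change reported under IFN-γ."""

    accession: str
    max_abs_fold: float

    def __post_init__(self) -> None:
        if self.max_abs_fold < 1:
            raise ValidationError(
                f"{self.accession}: max_abs_fold must be >= 1, got {self.max_abs_fold}"
            )


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        return list(reader)


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read an annotation TSV (columns accession, gene, tm, sp; 0/1 flags)."""
    records: dict[str, AnnotationRecord] = {}
    for row in _read_tsv(path, ("accession", "gene", "tm", "sp")):
        try:
            rec = AnnotationRecord(
                accession=row["accession"],
                gene=row["gene"],
                has_tm=bool(int(row["tm"])),
                has_sp=bool(int(row["sp"])),
            )
        except ValueError:
            raise ParseError(
                f"{path}: non-binary tm/sp flag for {row.get('accession')!r}"
            ) from None
        records[rec.accession] = rec
    return records


def read_transcript_table(path: str | Path) -> dict[str, TranscriptResponse]:
    """Read a transcript-response TSV (columns accession, max_abs_fold)."""
    records: dict[str, TranscriptResponse] = {}
    for row in _read_tsv(path, ("accession", "max_abs_fold")):
        try:
            fold = float(row["max_abs_fold"])
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric max_abs_fold for {row.get('accession')!r}"
            ) from None
        records[row["accession"]] = TranscriptResponse(row["accession"], fold)
    return records


def packaged_membrane_table_path() -> Path:
    """Path of the packaged membrane/secreted annotation transcription."""
    return Path(str(files("lfqpair").joinpath("data/membrane_secreted_annotations.tsv")))


def load_packaged_membrane_table() -> dict[str, AnnotationRecord]:
    """Load the packaged membrane/secreted annotation set."""
    return read_annotation_table(packaged_membrane_table_path())


def classify_membrane_secreted(
    calls: Iterable[ConsensusCall],
    annotations: Mapping[str, AnnotationRecord],
) -> dict[str, list[ConsensusCall]]:
    """Partition calls into membrane / secreted / other / unannotated.

    The four categories are disjoint and exhaustive; each call keeps its
    direction so downstream tables can separate gains from losses.
    """
    categories: dict[str, list[ConsensusCall]] = {
        CATEGORY_MEMBRANE: [],
        CATEGORY_SECRETED: [],
        CATEGORY_OTHER: [],
        CATEGORY_UNANNOTATED: [],
    }
    for call in calls:
        ann = annotations.get(call.accession)
        if ann is None:
            categories[CATEGORY_UNANNOTATED].append(call)
        elif ann.has_tm:
            categories[CATEGORY_MEMBRANE].append(call)
        elif ann.has_sp:
            categories[CATEGORY_SECRETED].append(call)
        else:
            categories[CATEGORY_OTHER].append(call)
    return categories


def crossref_transcript_response(
    calls: Iterable[ConsensusCall],
    table: Mapping[str, TranscriptResponse],
    min_fold: float = MIN_TRANSCRIPT_FOLD,
) -> dict[str, str]:
    """Flag each called accession as transcript-responsive or not reported.

    A protein is *responsive* iff it appears in the transcript table with
    an absolute fold change of at least ``min_fold`` (inclusive); proteins
    absent from the table, or below the threshold, are *not reported* —
    mirroring the (A)/(B) split of the published differential tables.
    """
    flags: dict[str, str] = {}
    for call in calls:
        entry = table.get(call.accession)
        flags[call.accession] = (
            RESPONSIVE
            if entry is not None and entry.max_abs_fold >= min_fold
            else NOT_REPORTED
        )
    return flags
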