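"""End-to-end orchestration: merge → identify → quantify → difference →
normalize → consensus → annotate.

:func:`analyze_experiment` is the in-memory core used by the library,
tests and examples; :func:`run_pipeline` is the file-based wrapper behind
the CLI, which reads PSM TSVs from a directory and writes every
intermediate table, a population-stats table, the consensus table,
annotation tables and a plain-text run report.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import annotation as ann
from .consensus import (
    DIR_DECREASED,
    DIR_INCREASED,
    MIN_PAIRS,
    MODE_UNIQUE_Z,
    Z_THRESHOLD,
    ConsensusCall,
    call_all,
)
from .differential import PairDifference, PopulationStats, central_stats, normalize, pair_differences
from .errors import ValidationError
from .identification import MIN_UNIQUE_PEPTIDES, PEPTIDE_LOG_E_MAX, PROTEIN_LOG_E_MAX
from .psm_io import CONDITIONS, RunTable, merge_fractions, read_psm_table
from .quantitation import ProteinQuant, quantify_run


@dataclass
class PipelineConfig:
    """Thresholds, options and paths of one pipeline run."""

    input_dir: str | None = None
    output_dir: str | None = None
    annotation_table: str | None = None
    transcript_table: str | None = None
    peptide_log_e_max: float = PEPTIDE_LOG_E_MAX
    protein_log_e_max: float = PROTEIN_LOG_E_MAX
    min_unique_peptides: int = MIN_UNIQUE_PEPTIDES
    z_threshold: float = Z_THRESHOLD
    min_pairs: int = MIN_PAIRS
    inclusive_threshold: bool = True
    robust_sd: bool = False
    mode_unique_rule: str = MODE_UNIQUE_Z
    donor_order: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.min_unique_peptides < 1 or self.min_pairs < 1:
            raise ValidationError("min_unique_peptides and min_pairs must be >= 1")
        if self.z_threshold <= 0:
            raise ValidationError(f"z_threshold must be > 0, got {self.z_threshold}")


@dataclass
class AnalysisResult:
    """All intermediate and final products of one analysis."""

    config: PipelineConfig
    quants: dict[tuple[str, str], list[ProteinQuant]]
    differences: dict[str, list[PairDifference]]
    stats: dict[str, PopulationStats]
    calls: list[ConsensusCall]
    donor_order: list[str]

    @property
    def increased(self) -> list[ConsensusCall]:
        return [c for c in self.calls if c.direction == DIR_INCREASED]

    @property
    def decreased(self) -> list[ConsensusCall]:
        return [c for c in self.calls if c.direction == DIR_DECREASED]


def analyze_experiment(
    runs: Mapping[tuple[str, str], RunTable],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full differential analysis on fraction-merged runs.

    ``runs`` maps (donor_id, condition) → :class:`RunTable`; every donor
    must contribute both conditions.
    """
    config = config or PipelineConfig()
    config.validate()
    donors = sorted({donor for donor, _ in runs})
    if config.donor_order:
        donors = [d for d in config.donor_order if d in donors]
    for donor in donors:
        for cond in CONDITIONS:
            if (donor, cond) not in runs:
                raise ValidationError(f"donor {donor!r} is missing its {cond} run")

    quants = {
        key: quantify_run(
            run,
            pep_log_e_max=config.peptide_log_e_max,
            prot_log_e_max=config.protein_log_e_max,
            min_unique_peptides=config.min_unique_peptides,
        )
        for key, run in runs.items()
    }
    differences: dict[str, list[PairDifference]] = {}
    stats: dict[str, PopulationStats] = {}
    for donor in donors:
        diffs = pair_differences(quants[(donor, "IFN")], quants[(donor, "CTL")])
        st = central_stats(diffs, robust=config.robust_sd)
        differences[donor] = normalize(diffs, st)
        stats[donor] = st
    calls = call_all(
        differences,
        donor_order=donors,
        z_threshold=config.z_threshold,
        min_pairs=config.min_pairs,
        inclusive=config.inclusive_threshold,
        mode_unique_rule=config.mode_unique_rule,
    )
    return AnalysisResult(
        config=config, quants=quants, differences=differences, stats=stats,
        calls=calls, donor_order=donors,
    )


def _quant_frame(quants: Sequence[ProteinQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (q.accession, q.donor_id, q.condition, q.log2_intensity,
             q.n_distinct_peptides, q.n_psms)
            for q in quants
        ],
        columns=["accession", "donor_id", "condition", "log2_intensity",
                 "n_distinct_peptides", "n_psms"],
    )


def _diff_frame(diffs: Sequence[PairDifference]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.accession, d.mode, d.D, d.Z, d.ifn_log2, d.ctl_log2) for d in diffs],
        columns=["accession", "mode", "D", "Z", "ifn_log2", "ctl_log2"],
    )


def _consensus_frame(calls: Sequence[ConsensusCall], donor_order: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [c.accession, c.direction, c.n_qualifying, *c.per_donor_display]
            for c in calls
        ],
        columns=["accession", "direction", "n_qualifying", *donor_order],
    )


def discover_runs(input_dir: str | Path) -> dict[tuple[str, str], RunTable]:
    """Read every ``psm_*.tsv`` in a directory and group rows into runs.

    Rows are grouped by their own (donor_id, condition) fields, so one
    file per run and one file per fraction both work; grouping is
    concatenation (fraction merging) with no de-duplication.
    """
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("psm_*.tsv"))
    if not paths:
        raise ValidationError(f"no psm_*.tsv files found in {input_dir}")
    grouped: dict[tuple[str, str], list] = {}
    for path in paths:
        for rec in read_psm_table(path):
            grouped.setdefault((rec.donor_id, rec.condition), []).append(rec)
    return {
        (donor, cond): merge_fractions([records], donor, cond)
        for (donor, cond), records in grouped.items()
    }


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Execute the pipeline from files and write all result tables.

    Reads PSM tables from ``config.input_dir``, writes per-run quant
    TSVs, per-donor difference TSVs, the population-stats table, the
    consensus table, annotation outputs (when annotation/transcript
    tables are configured) and a timestamped plain-text report embedding
    the resolved configuration, all under ``config.output_dir``.
    """
    config.validate()
    if not config.input_dir or not config.output_dir:
        raise ValidationError("input_dir and output_dir must be set")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"[{stamp}] {msg}")

    log(f"reading PSM tables from {config.input_dir}")
    runs = discover_runs(config.input_dir)
    log(f"found {len(runs)} runs: {sorted(runs)}")
    result = analyze_experiment(runs, config)

    for (donor, cond), quants in sorted(result.quants.items()):
        _quant_frame(quants).to_csv(outdir / f"quant_{donor}_{cond}.tsv", sep="\t", index=False)
    log(f"quantified {len(result.quants)} runs")

    for donor, diffs in sorted(result.differences.items()):
        _diff_frame(diffs).to_csv(outdir / f"differences_{donor}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (s.donor_id, s.central_mean, s.central_sd, s.n_central,
             s.n_ifn_only, s.n_ctl_only)
            for s in (result.stats[d] for d in result.donor_order)
        ],
        columns=["donor_id", "central_mean", "central_sd", "n_central",
                 "n_ifn_only", "n_ctl_only"],
    ).to_csv(outdir / "population_stats.tsv", sep="\t", index=False)
    log("computed per-donor differences and population stats")

    _consensus_frame(result.calls, result.donor_order).to_csv(
        outdir / "consensus.tsv", sep="\t", index=False
    )
    log(f"consensus: {len(result.increased)} increased, {len(result.decreased)} decreased")

    categories = flags = None
    called = result.increased + result.decreased
    if config.annotation_table:
        annotations = ann.read_annotation_table(config.annotation_table)
        categories = ann.classify_membrane_secreted(called, annotations)
        rows = []
        for category, calls in categories.items():
            for c in calls:
                rows.append((c.accession, c.direction, category))
        pd.DataFrame(rows, columns=["accession", "direction", "category"]).to_csv(
            outdir / "membrane_secreted.tsv", sep="\t", index=False
        )
        log(
            f"annotated: {len(categories['membrane'])} membrane, "
            f"{len(categories['secreted'])} secreted"
        )
    if config.transcript_table:
        table = ann.read_transcript_table(config.transcript_table)
        flags = ann.crossref_transcript_response(called, table)
        pd.DataFrame(
            sorted(flags.items()), columns=["accession", "transcript_response"]
        ).to_csv(outdir / "transcript_response.tsv", sep="\t", index=False)
        n_resp = sum(v == ann.RESPONSIVE for v in flags.values())
        log(f"transcript cross-reference: {n_resp}/{len(flags)} responsive")

    # Run report: counts plus the resolved configuration.
    quant_sets = {key: {q.accession for q in qs} for key, qs in result.quants.items()}
    shared = set.intersection(*quant_sets.values()) if quant_sets else set()
    report = [
        "paired label-free differential analysis report",
        "=" * 46,
        "",
        *log_lines,
        "",
        "counts",
        "------",
    ]
    for key in sorted(quant_sets):
        report.append(f"proteins quantified in {key[0]}/{key[1]}: {len(quant_sets[key])}")
    report.append(f"proteins quantified in all runs: {len(shared)}")
    for donor in result.donor_order:
        s = result.stats[donor]
        report.append(
            f"donor {donor}: central n={s.n_central} mean={s.central_mean:.4f} "
            f"sd={s.central_sd:.4f}, ifn_only={s.n_ifn_only}, ctl_only={s.n_ctl_only}"
        )
    report.append(f"increased calls: {len(result.increased)}")
    report.append(f"decreased calls: {len(result.decreased)}")
    if categories is not None:
        report.append(f"membrane: {len(categories['membrane'])}")
        report.append(f"secreted: {len(categories['secreted'])}")
    if flags is not None:
        report.append(
            f"transcript-responsive: {sum(v == ann.RESPONSIVE for v in flags.values())}"
            f"/{len(flags)}"
        )
    report += ["", "resolved configuration", "-" * 22, yaml.safe_dump(asdict(config), sort_keys=True)]
    (outdir / "report.txt").write_text("\n".join(report) + "\n", encoding="utf-8")
    with (outdir / "resolved_config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return result
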