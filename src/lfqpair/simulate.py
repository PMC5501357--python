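"""Synthetic PSM-level paired experiments with known ground truth.

The generator emulates the design of a paired label-free shotgun
experiment: 5 donors, each contributing an untreated (CTL) and a
treated (IFN) sample, each sample acquired as 21 concatenated
first-dimension fractions of PSM evidence.  The generative model is:

* protein baseline log2 abundance ~ Normal(``baseline_mean``, ``baseline_sd``);
* a per-donor, per-protein shift ~ Normal(0, ``donor_sd``) shared by both
  conditions of the pair (it cancels in the paired difference but moves
  proteins across the detection boundary donor by donor);
* the treated condition adds the spiked effect ``true_log2fc`` (0 for null
  proteins; exactly ``round(frac_de * n_proteins)`` proteins are non-null);
* per-condition measurement noise ~ Normal(0, ``noise_sd``/√2), so the
  paired difference of a both-mode protein has SD ``noise_sd``;
* protein intensity is split across its peptides by fixed per-peptide
  ionization weights (Dirichlet, shared across all runs);
* each peptide is detected with probability
  ``logistic(dropout_slope · (peptide_log2 − dropout_midpoint))`` — low
  abundance proteins drop below two detected peptides in one condition,
  which is what creates mode-unique proteins;
* each detected peptide yields ``1 + Poisson(psm_rate)`` PSMs sharing its
  intensity equally; each PSM draws ``peptide_log_e = −|Normal(0, σ)|``
  with σ solved so that a fraction ``frac_unconfident`` of PSMs fails the
  −1.5 confidence cut; PSMs land uniformly in fractions 1..21.

One pseudo-random stream is derived per run from (seed, donor, condition),
so adding donors does not perturb existing runs, and a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import ValidationError
from .identification import PEPTIDE_LOG_E_MAX
from .psm_io import PsmRecord, RunTable, write_psm_table

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimConfig:
    """Parameters of the synthetic paired experiment.

    Defaults reproduce the emulated study design: 5 donor pairs, 21
    fractions, and a pair-difference noise SD of 0.8 log2 units so that a
    2 SD change corresponds to ≈3-fold (2^1.6 ≈ 3.0).
    """

    n_donors: int = 5
    n_proteins: int = 2000
    n_fractions: int = 21
    frac_de: float = 0.1
    effect_log2fc: float = 2.0
    frac_up: float = 0.8
    noise_sd: float = 0.8
    donor_sd: float = 0.5
    baseline_mean: float = 14.0
    baseline_sd: float = 2.5
    peptides_min: int = 2
    peptides_max: int = 12
    ionization_alpha: float = 8.0
    dropout_midpoint: float = 6.0
    dropout_slope: float = 6.0
    frac_unconfident: float = 0.02
    psm_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValidationError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if not 0 <= self.frac_up <= 1:
            raise ValidationError(f"frac_up must be in [0, 1], got {self.frac_up}")
        if not 0 < self.frac_unconfident < 1:
            raise ValidationError(
                f"frac_unconfident must be in (0, 1), got {self.frac_unconfident}"
            )
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_donors < 1 or self.n_proteins < 1 or self.n_fractions < 1:
            raise ValidationError("n_donors, n_proteins and n_fractions must be >= 1")
        if not 2 <= self.peptides_min <= self.peptides_max:
            raise ValidationError(
                f"need 2 <= peptides_min <= peptides_max, got "
                f"({self.peptides_min}, {self.peptides_max})"
            )
        if self.dropout_slope <= 0 or self.donor_sd < 0:
            raise ValidationError("dropout_slope must be > 0 and donor_sd >= 0")
        if self.psm_rate < 0 or self.ionization_alpha <= 0:
            raise ValidationError("psm_rate must be >= 0 and ionization_alpha > 0")

    @property
    def donor_ids(self) -> tuple[str, ...]:
        return tuple(f"d{i + 1}" for i in range(self.n_donors))

    @property
    def log_e_sigma(self) -> float:
        """Scale of the −|Normal| expectation-score draw.

        Solved so that P(log_e > −1.5) = ``frac_unconfident``:
        P(|N(0, σ)| < 1.5) = frac_unconfident.
        """
        return -PEPTIDE_LOG_E_MAX / norm.ppf(0.5 + self.frac_unconfident / 2.0)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated protein."""

    accession: str
    true_log2fc: float
    baseline_log2: float
    #: (donor_id, condition) → whether >= 2 peptides had a confident PSM
    #: in that run (i.e. the protein is quantifiable there).
    detected: dict[tuple[str, str], bool] = field(default_factory=dict)


@dataclass
class SimulatedExperiment:
    """Generator output: per-run PSM tables plus the truth table."""

    config: SimConfig
    runs: dict[tuple[str, str], RunTable]
    truth: list[SyntheticTruth]


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    """Random tryptic-looking peptide sequences, globally distinct."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(9, 16))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return seqs


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate a full paired experiment under ``config``.

    Returns the per-run PSM tables (``n_donors`` × 2 runs) and the truth
    table.  Identical configs (including seed) give identical output.
    """
    config.validate()
    n = config.n_proteins

    # Truth layer: shared across all runs.
    truth_rng = np.random.default_rng([config.seed, 0])
    baseline = truth_rng.normal(config.baseline_mean, config.baseline_sd, n)
    n_de = round(config.frac_de * n)
    de_idx = truth_rng.choice(n, size=n_de, replace=False)
    signs = np.where(truth_rng.random(n_de) < config.frac_up, 1.0, -1.0)
    effects = np.zeros(n)
    effects[de_idx] = signs * config.effect_log2fc

    pep_counts = truth_rng.integers(config.peptides_min, config.peptides_max + 1, n)
    pep_protein = np.repeat(np.arange(n), pep_counts)
    n_peptides = int(pep_counts.sum())
    weights = np.concatenate(
        [truth_rng.dirichlet(np.full(m, config.ionization_alpha)) for m in pep_counts]
    )
    log2_weights = np.log2(weights)
    pep_seqs = _peptide_sequences(truth_rng, n_peptides)

    accessions = [f"SYN{i:05d}" for i in range(n)]
    truth = [
        SyntheticTruth(accession=accessions[i], true_log2fc=float(effects[i]),
                       baseline_log2=float(baseline[i]))
        for i in range(n)
    ]

    cond_noise_sd = config.noise_sd / math.sqrt(2.0)
    runs: dict[tuple[str, str], RunTable] = {}
    for d, donor in enumerate(config.donor_ids):
        donor_rng = np.random.default_rng([config.seed, 1, d])
        donor_shift = donor_rng.normal(0.0, config.donor_sd, n)
        for c, cond in enumerate(("CTL", "IFN")):
            rng = np.random.default_rng([config.seed, 2, d, c])
            prot_log2 = baseline + donor_shift + rng.normal(0.0, cond_noise_sd, n)
            if cond == "IFN":
                prot_log2 = prot_log2 + effects
            pep_log2 = prot_log2[pep_protein] + log2_weights
            p_detect = expit(config.dropout_slope * (pep_log2 - config.dropout_midpoint))
            detected = rng.random(n_peptides) < p_detect
            det_idx = np.flatnonzero(detected)

            n_psm = 1 + rng.poisson(config.psm_rate, det_idx.size)
            psm_pep = np.repeat(det_idx, n_psm)
            total = int(psm_pep.size)
            psm_intensity = (2.0 ** pep_log2[psm_pep]) / np.repeat(n_psm, n_psm)
            log_e = -np.abs(rng.normal(0.0, config.log_e_sigma, total))
            fractions = rng.integers(1, config.n_fractions + 1, total)
            charges = rng.choice([2, 3, 4], size=total, p=[0.6, 0.3, 0.1])

            records = [
                PsmRecord(
                    donor_id=donor,
                    condition=cond,
                    fraction=int(fractions[k]),
                    peptide_seq=pep_seqs[psm_pep[k]],
                    charge=int(charges[k]),
                    protein_accessions=(accessions[pep_protein[psm_pep[k]]],),
                    peptide_log_e=float(log_e[k]),
                    fragment_intensity=float(psm_intensity[k]),
                )
                for k in range(total)
            ]
            runs[(donor, cond)] = RunTable(donor_id=donor, condition=cond, records=records)

            # Truth-level detectability: >= 2 peptides with a confident PSM.
            conf_pep = np.zeros(n_peptides, dtype=bool)
            conf_psm = psm_pep[log_e <= PEPTIDE_LOG_E_MAX]
            conf_pep[conf_psm] = True
            n_conf = np.bincount(pep_protein[conf_pep], minlength=n)
            for i in np.flatnonzero(n_conf >= 2):
                truth[i].detected[(donor, cond)] = True
            for i in np.flatnonzero(n_conf < 2):
                truth[i].detected[(donor, cond)] = False
    return SimulatedExperiment(config=config, runs=runs, truth=truth)


def write_truth_table(truth: Sequence[SyntheticTruth], path: str | Path) -> None:
    """Write the truth table as a TSV (one detected_* column per run)."""
    path = Path(path)
    run_keys = sorted(truth[0].detected) if truth else []
    header = ["accession", "true_log2fc", "baseline_log2"] + [
        f"detected_{donor}_{cond}" for donor, cond in run_keys
    ]
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for t in truth:
            row = [t.accession, repr(t.true_log2fc), repr(t.baseline_log2)] + [
                str(int(t.detected[key])) for key in run_keys
            ]
            fh.write("\t".join(row) + "\n")


def write_experiment(sim: SimulatedExperiment, outdir: str | Path) -> None:
    """Write PSM TSVs (one per run), the truth TSV and the resolved config."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (donor, cond), run in sorted(sim.runs.items()):
        write_psm_table(run.records, outdir / f"psm_{donor}_{cond}.tsv")
    write_truth_table(sim.truth, outdir / "truth.tsv")
    with (outdir / "sim_config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(sim.config), fh, sort_keys=True)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Confusion summary of consensus calls against simulated ground truth."""

    n_true_nonzero: int
    n_called: int
    n_correct_direction: int
    n_null_called: int
    n_wrong_direction: int
    n_called_up: int
    n_called_down: int
    sensitivity: float
    #: None when no calls were made (false-discovery proportion undefined).
    fdp: float | None


def recovery_metrics(calls, truth: Sequence[SyntheticTruth]) -> RecoveryMetrics:
    """Score consensus calls against the generator's ground truth.

    sensitivity = called-with-correct-direction / truly-nonzero;
    FDP = called-but-null / called (None when nothing was called).
    Exact integer arithmetic throughout.

    Raises
    ------
    ValidationError
        If a called accession is not part of the truth universe.
    """
    from .consensus import DIR_DECREASED, DIR_INCREASED, DIR_NONE

    truth_by_acc = {t.accession: t for t in truth}
    unknown = [c.accession for c in calls if c.accession not in truth_by_acc]
    if unknown:
        raise ValidationError(f"calls outside the truth universe: {unknown[:5]}")

    n_true_nonzero = sum(t.true_log2fc != 0 for t in truth)
    n_called = n_correct = n_null = n_wrong = n_up = n_down = 0
    for call in calls:
        if call.direction == DIR_NONE:
            continue
        n_called += 1
        if call.direction == DIR_INCREASED:
            n_up += 1
        else:
            n_down += 1
        fc = truth_by_acc[call.accession].true_log2fc
        if fc == 0:
            n_null += 1
        elif (fc > 0) == (call.direction == DIR_INCREASED):
            n_correct += 1
        else:
            n_wrong += 1
    return RecoveryMetrics(
        n_true_nonzero=n_true_nonzero,
        n_called=n_called,
        n_correct_direction=n_correct,
        n_null_called=n_null,
        n_wrong_direction=n_wrong,
        n_called_up=n_up,
        n_called_down=n_down,
        sensitivity=(n_correct / n_true_nonzero) if n_true_nonzero else 0.0,
        fdp=(n_null / n_called) if n_called else None,
    )
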