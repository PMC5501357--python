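# Methods

## Scope and data model

The pipeline consumes tabulated search-engine output: one row per
peptide-spectrum match (PSM) with donor, condition (CTL/IFN), fraction,
stripped peptide sequence, mapped accessions, base-10 log expectation
score and summed MS/MS fragment intensity.  Raw spectra, the database
search itself, retention times and FDR/decoy machinery are out of scope;
the analysis starts where the search engine stops.  Fraction files are
evidence partitions only and are merged by concatenation with no
spectrum-level de-duplication — repeat PSMs of one peptide are retained
as independent evidence (dynamic exclusion at acquisition already limits
repeats, and collapsing them would silently change the intensity sums).

## Identification and quantifiability

Peptide uniqueness is evaluated per run against the accessions appearing
in that run's table: a peptide is unique iff the union of its PSMs'
accession lists is a single protein.  This is the only self-contained
definition available when no search FASTA is distributed with the
tables; it makes uniqueness slightly permissive in runs where a
competing protein was not observed at all.  Modifications are ignored
("distinct" means distinct stripped sequence).

A protein is confidently identified when ≥ 2 distinct unique peptides
each have a PSM at log(e) ≤ −1.5 and, when a protein-level score was
exported, protein log(e) ≤ −3.  Both cut-offs are inclusive.  The
protein-level clause is vacuous when the score is absent, so the
pipeline runs from minimal PSM tables.  The same two-unique-peptide rule
defines quantifiability, so every emitted quantity rests on at least two
independent sequences.  All three thresholds are configurable
(`peptide_log_e_max`, `protein_log_e_max`, `min_unique_peptides`).

Quantitation sums natural fragment intensities over the confident PSMs
of unique peptides and then takes log2 (sum-then-log, not sum of logs).
Shared-peptide intensity is excluded: the two-non-redundant-peptide rule
implies unique-peptide accounting, and counting shared signal under
several accessions would double-count it.  A non-positive sum drops the
protein with a dedicated error.

## Paired differences and normalization

Per donor, `D = log2(IFN) − log2(CTL)` over the union of quantified
proteins.  Mode-unique proteins (quantifiable in exactly one condition)
take the signed log2 intensity of the observed side: `D = +log2(IFN)`
for IFN-only, `D = −log2(CTL)` for CTL-only.  Detected proteins carry
large positive log2 intensities, so this reproduces the observed
structure of two outer populations flanking a central one.  The signed-
intensity convention is this package's choice — a presence/absence event
has no canonical difference value — and its magnitude is only meaningful
as "far outside the central population".

Each donor's central (both-mode) population is summarized by its sample
mean and sample SD (n−1 denominator), and all three populations are
standardized by those two numbers.  Normalization is strictly per donor:
each pair has its own scale.  After normalization the central population
has sample mean 0 and sample SD 1 exactly (tested to 1e−9); Z is
strictly increasing in D, and shifting both conditions of a pair by a
constant leaves both-mode Z unchanged.

A robust alternative (`robust_sd=True`: median and 1.4826·MAD) is
provided but off by default.  The estimator choice matters when a
substantial fraction of proteins is genuinely changed: spiked proteins
sit inside the central population whenever they are detected in both
conditions, so the classical sample SD absorbs them and grows, raising
the effective |2 SD| bar and costing sensitivity.  The recovery
benchmark (`examples/05_recovery_benchmark.py`, and the acceptance
script) quantifies this on simulations with 10% of proteins changed at
three times the noise SD: the classical scale lands near 1.1–1.25 log2
units instead of 0.8 and recovers roughly sixty percent of spiked
proteins, while the robust scale recovers most of them at the same
false-discovery level.  The classical estimator remains the default
because the normalization contract (central population standardized
*exactly*) is defined in terms of sample statistics; analysts expecting
many true changes should enable the robust option.

Degenerate inputs: fewer than two both-mode proteins, or a central
population with zero spread, abort the donor with an explicit
insufficient-data error — no fallback scale is invented.

## Consensus calls

A donor qualifies *up* at Z ≥ 2 and *down* at Z ≤ −2 (inclusive; both
the threshold and inclusivity are configurable).  Mode-unique
observations qualify in the direction of their mode, gated by the same
|Z| threshold on the common scale; a configurable alternative
(`mode_unique_rule="always"`) accepts any quantifiable mode-unique
observation.  A protein is called when ≥ 3 of 5 donors qualify in the
same direction.  Counting is no-veto: donors qualifying in the opposite
direction, or not at all, are simply not counted — with 5 donors and a
majority requirement the two directions can never both reach the bar.
Display rows mirror the published convention: fold change `2^D` rounded
to one decimal (fold *decrease* `2^(−D)` in decreased-direction tables),
`IFN`/`CTL` for single-condition detections, `–` for proteins absent
from a donor.

## Annotation

Membrane/secreted classification and transcript-responsiveness flags are
applied from local TSVs only; nothing is fetched live.  Classification:
membrane = any transmembrane region (regardless of signal peptide),
secreted = signal peptide without a transmembrane region, other =
neither, unannotated = not in the table.  The transcript rule is an
inclusive absolute fold change ≥ 2.  Curation of the transcript table
(species and tissue restrictions of the underlying database query) is an
upstream concern.  A transcription of the published membrane/secreted
table (47 transmembrane-flagged and 17 signal-peptide-only proteins)
ships with the package and serves as a worked classification example.

## Synthetic experiments

The generator emulates the study design — 5 donors × {CTL, IFN} × 21
fractions of PSM evidence — with known ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2000 | proteome size |
| `frac_de` | 0.1 | fraction of proteins with a true effect |
| `effect_log2fc` | 2.0 | spiked effect magnitude (log2 units) |
| `frac_up` | 0.8 | fraction of spiked effects that are inductions |
| `noise_sd` | 0.8 | pair-difference noise SD (log2) |
| `donor_sd` | 0.5 | per-donor, per-protein abundance shift (log2) |
| `baseline_mean`, `baseline_sd` | 14.0, 2.5 | protein log2 abundance distribution |
| `peptides_min..max` | 2..12 | peptides per protein (uniform) |
| `ionization_alpha` | 8.0 | Dirichlet concentration of peptide weights |
| `dropout_midpoint`, `dropout_slope` | 6.0, 6.0 | logistic peptide detection vs log2 intensity |
| `frac_unconfident` | 0.02 | PSM fraction failing the −1.5 confidence cut |
| `psm_rate` | 1.0 | extra PSMs per detected peptide (Poisson) |

Protein intensity is split across peptides by fixed ionization weights
shared across runs; each peptide is detected with a logistic probability
of its log2 intensity; detected peptides emit `1 + Poisson(psm_rate)`
PSMs splitting the peptide intensity equally; PSM scores are
`−|Normal(0, σ)|` with σ solved so `frac_unconfident` of PSMs fails the
−1.5 cut.  Donor shifts are shared by both conditions of a pair (they
cancel in D but move proteins across the detection boundary donor by
donor); per-condition noise is `noise_sd/√2` so the both-mode difference
has SD `noise_sd`.  One random stream is derived per run from
(seed, donor, condition), so adding donors never perturbs existing runs
and a fixed seed yields byte-identical files.

`noise_sd = 0.8` is anchored to the ~3-fold interpretation of the 2 SD
threshold (2^(2·0.8) ≈ 3.0).  The measurement-layer defaults (dropout
geometry, weight concentration, score confidence, PSM rate) were set so
that the measurement stage contributes only second-order variance and
null simulations realize a central SD close to `noise_sd`
(2^(2·SD) ≈ 3.1).  This is a deliberate trade-off: with these defaults
~94% of proteins are quantified in every run, whereas a real 2D-LC
experiment of this depth shares only about half of its identifications
across ten runs.  Raising the missingness to realistic levels (whether
abundance-dependent or random) necessarily widens the central difference
population beyond `noise_sd` — run-to-run missingness and a tight
difference distribution cannot coexist in this model — so passing tests
demonstrate the analysis on data whose between-run reproducibility is
better than real acquisitions.  The generator likewise does not simulate
shared (non-unique) peptides, modifications, retention behaviour or
search-engine score–intensity correlation.

Frozen null envelopes (precomputed over 50 null replicates, seeds 1..50,
1000 proteins): at most 10 consensus calls per 1000 null proteins
(mean 3.2), and a maximum Kolmogorov–Smirnov statistic of 0.039 for the
central Z against N(0, 1) — tests assert 0.05.

## Numerical choices

- Intensity sums use compensated summation (`math.fsum`); aggregation is
  permutation-invariant and fraction-partition-invariant, and doubling
  all intensities shifts every log2 value by exactly +1.
- Fold display uses Python's round-half-even formatting to one decimal.
- Ties at thresholds are inclusive everywhere (log(e) ≤ −1.5/−3, |Z| ≥ 2,
  transcript fold ≥ 2), matching the "or lower"/"at least" phrasing of
  the conventions being implemented.
- Accession-sorted, donor-ordered outputs make every stage deterministic
  on fixed inputs; the acceptance script derives all simulation seeds
  from its `--seed` argument.

## Known limitations

- Per-run uniqueness can over-credit peptides when a homologous protein
  is absent from a run; protein grouping/parsimony beyond the
  unique-peptide rule is not attempted.
- Outer-population Z-scores are ordinal, not probabilistic; the
  mode-unique qualification rule is a convention (gated by |Z| by
  default), not an inference.
- No multiple-testing control is applied — the consensus rule's error
  behaviour is characterized empirically by the null envelope instead.
- The synthetic data's between-run reproducibility is optimistic (see
  above), so absolute sensitivity/FDP figures from simulations should
  not be read as estimates for real experiments with realistic
  missingness.
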