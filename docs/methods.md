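# Methods

This note documents the model implemented by `nbclass`, its assumptions, the
parameters that matter, the synthetic data used to validate it, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Labeling model

The response readout is EC50 in µM, mapped to the −log10 molar scale
(score = 6 − log10(EC50 µM)). Classification is three-zone with *strict*
inequalities: a score exactly equal to a cutoff is ambiguous. Ambiguous cell
lines are excluded before any training or testing, so the learning problem
is strictly binary; only regression-style predictors can re-introduce an
ambiguous call at prediction time.

Clinical cutoffs, θ_res = −log10(1.5·C_max) + 6 and
θ_sens = −log10(C_max/1.5) + 6 with C_max in µM, always differ by
2·log10(1.5) ≈ 0.35218. An optional floor clamps both cutoffs to at least
5.0 (−log10 of 10 µM, a typical maximum screened dose); this is on by
default because published cutoff tables bottom out there, and can be
disabled (`clamp_floor=None`).

Statistical cutoffs use the mean µ and SD σ of the EC50 distribution in µM:
θ = −log10((µ ± 0.3σ)·10⁻⁶). Two points were underdetermined and are
exposed as switches:

* **Sample vs population SD** — sample SD (ddof=1) by default, `ddof=0`
  available. At screening-panel sizes the difference is negligible.
* **Scale of µ, σ** — computed on µM concentrations by default; an
  alternative reading computes them on the −log10 molar scores
  (`on_neglog_scale=True`), in which case the cutoffs are µ ∓ 0.3σ directly.
  The µM reading is the default because it needs no re-interpretation of
  the formula's −log.

µ − 0.3σ ≤ 0 (possible for extremely dispersed positive data) leaves the
sensitive cutoff undefined and raises a domain error rather than guessing.

Drugs whose labeling leaves fewer than `min_per_class` cell lines in either
class are excluded (`filter_balanced_drugs`); a one-sided class distribution
cannot support training or stratified validation.

## Feature selection

Quantization splits the observed [min, max] range of a gene into *t*
equal-width intervals, the maximum value closing the last interval; constant
genes collapse to a single term. The number of terms *t* is not dictated by
the method itself; the default is **t = 10**, a standard discretization
granularity, and results should be reported together with *t*. The χ² score
uses expected counts E = n·P_term·P_class; cells with E = 0 force A = 0 and
contribute zero, avoiding pseudo-counts. Ranking ties break
lexicographically by gene symbol so selection is reproducible.

Quantization ranges and counts are computed from whatever samples the caller
passes — in the evaluation protocol that is always the training portion of a
fold, never the full dataset, which is the leakage-safe choice (the
alternative, dataset-wide ranges, would let test samples shift bin
boundaries).

Candidate-list selection (e.g. pro-/anti-apoptotic genes from a Gene
Ontology export) consumes plain text files; the "both" list is the set
union, since genes can carry both annotations. Random selection is the null
baseline: a uniform draw without replacement, reproducible from its seed.

## The classifier

Per class, the network has an edge wherever |Pearson r| exceeds the
threshold ε strictly; correlation with a constant vector is defined as 0.
Estimating correlations needs at least 3 samples per class. Per-node
predictors:

* **Ridge** (default): intercept-including, penalty λ = 10⁻³ globally. The
  intercept is included because expression levels are not centered; an
  intercept-free fit would conflate the mean level with the co-expression
  signal.
* **SVR (RBF)**: per-node grid search over C, γ ∈ {0.1, 1, 10} with the
  ε-tube fixed at 0.1, scored by k-fold CV mean squared error on the class's
  training samples (MSE is the natural aggregate for "closest to the actual
  expression level"). One seeded split is shared by all nodes of a fit call
  — re-splitting per node would multiply cost without changing what is
  estimated. Ties break toward the smallest C, then the smallest γ
  (preferring the least complex model). If a class has fewer samples than
  folds, the fold count drops to the sample count with a warning.

**Degree-0 nodes** predict their training-class mean — the natural
zero-covariate regression; nothing in the MSE rule requires every node to
have neighbors. **MSE ties** resolve to resistant: arbitrary but fixed, a
measure-zero event on continuous data that must still be deterministic.
The correlation threshold and the SVR tube are distinct parameters and are
named `corr_threshold` and `epsilon`/`svr_epsilon` throughout.

Models serialize to a JSON archive (gene order, threshold, edge lists,
ridge coefficients or SVR dual form with support vectors, fallback means).
SVR prediction is computed from the dual form,
f(x) = Σ αᵢ·exp(−γ‖svᵢ − x‖²) + b, which the tests verify against the
library implementation to 1e-10, so a round trip reproduces predictions
bit-exactly without pickling.

## Evaluation protocol

Double nested k-fold CV (default 5/5) with repeats. Both levels are
**stratified by class**: with the class sizes typical of per-drug screens,
unstratified random partitions frequently lose a class from some fold, which
would make the protocol undefined; stratification is therefore a documented
deviation from plain random partitioning. Infeasible configurations (a class
smaller than the fold count) raise an infeasibility error, which the
per-cancer-type evaluation surfaces as `"insufficient"` — the same filter
that removes drug/tissue combinations too small to validate.

The inner CV tunes one outer parameter (for NBC, ε over
{0.40, 0.46, …, 0.94}) by balanced accuracy, ties keeping the earliest grid
entry. Feature selection runs inside every estimator fit, so inner folds are
leakage-free as well; an instrumented-predictor test asserts that no
predicted sample id was ever seen by the fit that produced the prediction.
Metrics average over folds, then over repeats; reported SDs are across
repeats. All randomness derives from (seed, repeat, fold) via
`numpy.random.SeedSequence`, so a report is bit-reproducible from its seed.

MCC is computed on the 2×2 part of the confusion; ambiguous columns are
dropped with a warning (only hard classifiers have a clean MCC). The ROC
decision score for NBC is mse_resistant − mse_sensitive, the canonical
margin of the MSE rule. The repeat count defaults to 10 in tests and
examples; the full-scale protocol value of 100 is a config knob
(`n_repeats`).

## Synthetic data

The generator produces the structure the classifier assumes: classes that
differ in *which genes co-vary*, not in marginal expression. Genes are
assigned to blocks (balanced, interleaved); within a class, block mates
share a latent factor. The resistant class reshuffles the block assignment
of a fraction `block_assignment_divergence` of genes (a seeded permutation
of their labels) — at divergence 0 the classes are exchangeable, at 1 the
assignments are unrelated up to chance coincidence. Expression is

    x = baseline_gene + a_g·G_sample + a_b·Z_block,sample + noise_sd·ε

with loadings solved so that pairwise correlation is `within_block_corr`
(default 0.9) inside blocks and `background_corr` (default 0.5) across
blocks. The global factor G emulates the genome-wide covariation component
of real transcriptomes (housekeeping/technical variation shared by all genes
and both classes); it is what gives low correlation thresholds their
characteristic failure mode — dense, uninformative graphs — while high
thresholds prune true block edges, so accuracy peaks at intermediate ε.
Baselines (N(8, 2), shared across classes) set realistic expression levels
without adding class signal; per-gene means and variances are identical
across classes by construction.

EC50 scores are drawn per class around centers `ec50_separation` apart
(default 1.0 on the −log10 scale), with SD `ec50_noise_sd` = 0.3 around a
midpoint centered between the cutoffs — enough scatter that all three zones
are populated, as in real screens. Defaults are 100 genes, 100 cell lines
per class, 5 blocks.

What the generator does **not** emulate: heavy-tailed expression noise,
batch effects, cancer-type substructure, dose–response curve fitting error,
or correlated EC50/expression noise. Passing the recovery tests therefore
shows that the implementation detects class-specific covariance when it is
present and does not hallucinate it when absent — not that the method
attains any particular accuracy on real screens.

## Numerical choices and edge cases

* Expression values are used as provided — no normalization or z-scoring;
  the matrix is treated as opaque real units (an upstream log transform is
  the user's choice).
* Rows with missing values are dropped at load (with a warning) when
  explicitly allowed; otherwise missing or non-numeric cells are errors that
  name the offending gene/cell line.
* Alignment of expression columns to response records sorts cell lines
  lexicographically, so downstream partitions depend only on the seed.
* Duplicate gene rows collapse to the first occurrence with a warning;
  duplicate (cell line, drug) response records are an error (no principled
  way to pick one).
* Edge comparisons use strict `>` everywhere (correlation threshold, label
  zones, grid-search improvement, contribution counting), making boundary
  behavior explicit and testable.

## Known limitations

* Networks are undirected, unsigned, correlation-thresholded graphs; no
  partial correlations, no multi-class response levels.
* Per-node SVR with grid search is O(m′ · |grid| · folds) model fits per
  class and is the dominant cost at scale.
* The publication-evidence side of the biological-relevance analysis
  (literature co-occurrence counts) is out of scope; the package exports the
  per-gene prediction success rates that analysis consumes.
* Statistical cutoffs assume the EC50 distribution is meaningfully
  summarized by (µ, σ); heavy censoring at the screened dose range violates
  this.
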