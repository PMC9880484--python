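# Methods

This note documents the models, estimators and numerical conventions
implemented in `crosstaxa`, the choices made where several defensible
options existed, and what the synthetic testbed can and cannot establish.

## The cross-prediction protocol

The unit of analysis is a (predictor set, target) pair. Predictor sets are
the four multivariate tables — bacterial OTU counts, fungal OTU counts
(both CSS-normalized before entering the forest), plant percent cover, and
the environment table (plot age, seasonal mean soil temperature, soil pH).
Targets are twenty univariate plot-level variables (7 plant, 5 bacterial, 5
fungal, 3 environmental); a predictor never models a target from its own
group, giving 15 + 15 + 13 + 17 = 60 models.

Each model runs R = 10 Monte Carlo cross-validation repeats: a uniformly
random 80 % of plots (train size = round(0.8·n)) trains a random-forest
regressor, the held-out 20 % is predicted, and predicted versus observed
values are correlated. We report

* **accuracy of prediction** — the mean Pearson r over valid repeats, and
* **significance frequency** — the fraction of the R repeats whose
  correlation is significant at two-sided p < 0.05, with
  p from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.

These repeats are random holdouts, not disjoint folds; a classic k-fold
partition is available via `strict_folds=True` for comparison. A repeat
whose test observations or predictions are constant has no defined
correlation: it is recorded as missing, excluded from the accuracy mean,
counted as non-significant, and surfaced through `n_valid_repeats` — silent
NaN propagation would otherwise corrupt the frame series.

Forest hyperparameters follow regression conventions: 500 trees, feature
subset of ⌈p/3⌉ per split, unlimited depth, bootstrap resampling, no
tuning. (Tests and the acceptance script use smaller forests and feature
counts; the statistics are means and frequencies whose behaviour does not
depend on forest size beyond variance.)

Seeding: every stochastic step derives a child seed from the base seed plus
string tokens (predictor group, target name, repeat index, frame
identifier, plot id) through a BLAKE2 hash. Results are therefore
independent of execution order and safe to parallelize.

## Target derivation

* **Composition PCs.** Column-centered, unscaled PCA (covariance PCA, the
  convention for community tables); the first two axes and their variance
  fractions are kept. Axis signs are fixed so the largest-magnitude loading
  of each axis is positive, making output backend-independent. Microbial
  count tables (OTU and functional) are CSS-normalized before ordination;
  plant cover and plant functional tables enter untransformed. Raw and
  Hellinger transforms are available for sensitivity runs.
* **CSS normalization.** Per sample, the scaling factor is the cumulative
  sum of counts up to the sample's *l*-th quantile of its positive counts;
  samples are divided by their factor and rescaled by the median factor.
  Default l = 0.5; an adaptive mode picks the smallest quantile before the
  median absolute deviation of sample quantiles from their across-sample
  median starts growing by more than 10 % per step (an instability
  criterion). All-zero samples pass through unscaled with a warning.
* **Microbial Shannon.** Counts are rarefied to the minimum per-plot read
  total by multivariate-hypergeometric subsampling (without replacement),
  and Shannon H (natural log) is averaged over 999 repeats by default.
  Per-plot child seeds make the result independent of plot iteration order.
* **Plant functional composition.** For each of the nine categorical
  traits, per-level summed cover (the default trait set has level counts
  4+6+3+5+3+4+6+3+5 = 39, so the table has 39 category columns), merged
  with community-weighted means (CWM = Σ aₖtₖ/Σ aₖ) of the four measured
  continuous traits.
* **Faith's PD.** Sum of branch lengths of the minimal subtree spanning the
  plot's species; the root is included by default (the common toolchain
  default), with a flag to anchor at the MRCA instead.
* **FDis.** Gower dissimilarity on mixed traits (range-normalized
  continuous, 0/1 categorical, equal weights), an elementwise square-root
  correction for non-Euclidean dissimilarities (Cailliez and no correction
  are exposed), principal-coordinate embedding keeping real and imaginary
  parts, then the abundance-weighted mean distance of species to the
  abundance-weighted centroid. Species without trait coverage are dropped;
  a single covered species gives 0.

## Moving frames, trends, contrasts

Frames are contiguous windows of 45 plots in successional order stepped by
one plot; 135 plots yield 91 frames identified by their median plot
(23…113), and each repeat trains on 36 and tests on 9 plots. Frames are
defined on the full plot sequence; plots missing from a particular table
pair shrink that frame (splits scale as round(0.8·n)), and frames below 10
usable plots are skipped with a warning. Even windows need an explicit
lower-median rule.

Accuracy-versus-frame series are fit by OLS, linear and quadratic in the
frame identifier; the form with the higher **adjusted** r² is selected and
flagged significant when the overall F-test has p < 0.05. Fewer than 10
non-missing frames yields a distinct "no fit" result. An exact fit (zero
residual variance) is reported with p = 0.

Predictor groups are compared on frame-wise accuracies by one-way ANOVA
followed by Tukey's HSD at family-wise α = 0.05. The frame series overlap
by construction (44 of 45 plots shared between neighbours), so these
observations are strongly non-independent; the comparison implements the
frame-wise protocol faithfully and its p-values should be read as
descriptive, not as calibrated error rates.

## The synthetic chronosequence

The generator emulates the processed data of a 135-plot glacier forefield:

* **Gradient and environment.** The latent gradient g is the plot index
  rescaled to [0, 1]. Plot age follows a piecewise-linear interpolation
  over eight dated breakpoints (2–170 years), mimicking the uneven
  age–position relationship of a retreating glacier. Temperature rises
  (3.5 → 8 °C) and pH falls (8.3 → 6.3) monotonically with age, each plus
  Gaussian noise (sd 0.15 by default).
* **Communities.** Taxon k responds to the gradient through a Gaussian
  niche exp(−(g−μₖ)²/2w²), optimum μₖ uniform on [0, 1], shared breadth
  w = 0.15 — enough turnover that plot age is recoverable from any table.
  Default feature counts mirror the emulated study (4986 bacterial OTUs,
  5701 fungal OTUs, 99 plant species); tests and the acceptance script use
  scaled-down counts (tens to 150 features), which preserves every
  qualitative behaviour.
* **Counts and cover.** Microbial counts are negative binomial (dispersion
  size = 5) around depth-scaled relative abundances with per-plot depth
  LogNormal(9.2, 0.5) (≈5–50k reads), so CSS and rarefaction are
  non-trivial. Plant cover is expected abundance times log-normal noise,
  with small values zeroed to create realistic absences.
* **Coupling.** Each microbe is assigned κ = 3 plant partner species; its
  expected abundance is multiplied by max(0, 1 + coupling·z̄) where z̄ is
  the partners' mean standardized cover. Coupling acts plant→microbe only:
  the analysis never infers direction, so one directed mechanism suffices
  to create mutual statistical signal. At coupling = 0 microbial tables
  are conditionally independent of the plant table given the gradient.
* **Traits and phylogeny.** Nine categorical traits (2–6 levels, level
  counts summing to 39) and four log-normal continuous traits (height,
  leaf area, leaf weight, SLA); a pure-birth (Yule) tree whose tips are
  exactly the plant species, with no branch above the root. Functional
  tables aggregate OTUs into pathway/guild-like categories by a seed-keyed
  hash of the OTU name, conserving per-plot totals and invariant to column
  order.
* **Missing data.** Optional per-table random plot drops (off by default)
  emulate incomplete sampling; alignment intersects plots per table pair
  and logs the n used.

What the testbed does *not* emulate: phylogenetic or trait signal in niche
optima, spatial autocorrelation, compositional closure artefacts of
percent cover, or realistic OTU abundance distributions beyond
lognormal-niche × negative-binomial noise. Passing tests therefore show the
estimators and their calibration are correct under a known
generating process, not that any particular field system behaves this way.

## Calibration and recovery conditions

Two simulation suites define the package's statistical guarantees, at sizes
chosen to keep the full suite in the minutes range:

* **Null calibration** — coupling = 0, 100 scenario seeds, a 60-plot,
  40-OTU bacterial table predicting an independent white-noise target:
  mean accuracy within ±0.05 of 0 and mean significance frequency ≤ 0.08
  (nominal 0.05 plus Monte Carlo slack).
* **Coupling ladder** — coupling ∈ {0, 0.5, 1, 2}, 20 seeds each, 135
  plots; plants are generated with an effectively flat niche (width 10⁶)
  so that plant composition carries no gradient signal and any
  predictability of plant PC1 from bacteria is attributable to coupling
  alone. Mean accuracy rises strictly with coupling (≈0 → ≈0.45). With
  gradient-structured plants the shared gradient already saturates
  cross-group accuracy, which is why the ladder uses the decoupled
  variant.

## Known limitations

* The Tukey comparison inherits pseudoreplication from overlapping frames
  (see above).
* CSS quantile behaviour on very sparse samples depends on the positive-
  count quantile convention documented here; other implementations differ
  in how they treat zeros.
* The trend selector compares only linear and quadratic forms; genuinely
  non-polynomial accuracy profiles are summarized by whichever fits better.
* FDis with the "none" correction can discard negative-eigenvalue variance
  for strongly non-Euclidean trait spaces; the square-root default avoids
  this in practice.
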