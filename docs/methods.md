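# Methods

`compobench` is a simulation benchmark: it generates microbiome
intervention data with a known ground truth, observes that truth through
the compositional bottleneck of amplicon sequencing, and measures how much
the standard normalizations distort two downstream readouts —
per-taxon differential-abundance detection and community-level variance
explained. Everything below is the package's own account of the model,
its parameters, and the design choices where the design was open.

## Generative model

**Community archetype.** A community of `n_taxa = 100` taxa whose absolute
abundances are `exp(Normal(μ, σ))` with `μ = 12.5`, `σ = 2.5` (natural
log). This yields a handful of dominant taxa and a long tail of rare
ones, resembling a genus-level human gut profile. The absolute scale is
arbitrary: every downstream quantity is either computed within-sample
(compositions, CLR) or is scale-free (rank tests, correlations), so only
σ matters materially.

**Subjects.** Each of the 20 subjects (10 control, 10 treatment) is a
multiplicative variant of the archetype: abundance × `exp(Normal(0,
0.5))`, independent per subject and taxon. Sharing the archetype makes
log-abundances positively correlated between subjects taxon-wise, with
expected Pearson correlation σ²/(σ² + 0.5²) ≈ 0.962 — the correlation
structure of real cohorts, rather than taxa simulated independently.
The deviation is multiplicative (equivalently, additive on the log
scale) because a literal zero-mean normal multiplier would produce
negative abundances.

**Treatment.** One scenario is a triple (direction regime, effect size
`e`, proportion responding `p`). Exactly `round(p × n_taxa)` responder
taxa are drawn uniformly once per scenario iteration and shared by all
treatment subjects (a population-level response). Up-responders are
multiplied by `(1 + e)`, down-responders divided by `(1 + e)` — the
`(1 + e)` convention keeps every effect in the unidirectional regime an
increase (literal multiplication by e.g. 0.1 would be a decrease) and is
symmetric on the log scale for the bidirectional regime, which splits
responders 1:1 (the odd taxon goes to the increasing side). The grid is
`e ∈ {0.1, 0.5, 1, 5, 10}` × `p ∈ {1, 5, 10, 25, 50, 75}%`, 30 scenarios
per regime.

**Temporal noise.** Between the two timepoints, every taxon in every
subject (both arms) is multiplied by an independent `Uniform(0.75, 1.25)`
draw. A log-symmetric alternative `exp(Uniform(−log 1.25, +log 1.25))`
is available behind `log_symmetric_noise`. Noise applies once, to the
transition: the baseline observation is the subject profile itself.

**Sequencing.** Per sample, a library size is drawn from
`Normal(50000, 10000)` (rounded; non-positive draws redrawn) and reads
are allocated by a single multinomial draw with probabilities
proportional to the sample's absolute abundances. The multinomial was
chosen because it conserves the fixed read budget — exactly the
constant-sum constraint under study; a Poisson-per-taxon model would
not. Sampling zeros can occur for rare taxa even though the community
itself has none; no sparsity or zero-inflation is modelled beyond that,
and there is no sequencing-error, chimera, or rarefaction layer.

## Normalizations

Four transformations of the count table, plus the un-transformed
absolute matrix as the ground-truth representation:

* **relative** — counts / library size;
* **clr** — `log(x + c) − mean(log(x + c))` per sample; the pseudocount
  `c = 0.5` is added only when the matrix contains zeros;
* **tmm** — edgeR's scaling-factor algorithm: reference sample by the
  75th-percentile criterion, per-taxon log2 ratios (M) doubly trimmed
  (30% on M, 5% on A) and averaged with inverse delta-method variances,
  factors rescaled to geometric mean 1, counts divided by
  (library size × factor). Verified to 1e-6 against edgeR
  `calcNormFactors` on a frozen toy matrix;
* **deseq** — median-of-ratios size factors `exp(median(log x −
  log geomean))` over taxa positive in all samples (falling back to
  positive-count-only geometric means if sequencing zeros empty that
  set), counts divided by the factor. Verified to 1e-8 against DESeq2
  `estimateSizeFactorsForMatrix`. The median is taken on the log scale,
  which matters only for even taxon counts (the two middle ratios are
  averaged geometrically, matching the reference).

## Differential-abundance detection and scoring

The per-subject response is the between-timepoint change: the difference
of CLR values on the CLR scale, and the log-ratio `log(post/baseline)`
on every other scale (a plain-difference and a post-only mode are
config-exposed; see "Open choices"). Per taxon, treatment and control
responses are compared with a two-group Kruskal–Wallis test
(tie-corrected H, chi-squared reference with 1 df; a fully tied taxon is
defined as H = 0, p = 1). The row-wise test is vectorized in-house —
three million scalar `scipy.stats.kruskal` calls would dominate a full
grid run — and is tested to 1e-10 against scipy per row. p-values are
Benjamini–Hochberg adjusted across the 100 taxa of each dataset
(per method, per scenario, per iteration), cutoff adjusted p < 0.1. No
prevalence filtering: all-zero taxa are tied, hence never significant.

Detections are scored against the truth table. The default rate
convention divides each error count by **twice its own class size**:
`FP / (2 × non-responders)` and `FN / (2 × responders)` — half the
false-alarm and miss rates — so a fully misdetected class scores exactly
0.500 at any response proportion, which is the saturation value the
benchmark's error tables exhibit. A `total_taxa` convention
(errors / 100) is available behind `rate_convention`. Note the
convention changes the *weighting* of scenarios in grid averages, not
which taxa are misclassified.

## Community variance

PERMANOVA runs on the 20 post-intervention samples with the two-level
group factor (change-vectors are config-exposed in principle but
Bray–Curtis is undefined on negatives, so post-only is the default
subset). Total sum of squares `Σ_{i<j} d²/n` is partitioned into within-
and between-group parts; R² is the between fraction and needs no
permutations (`n_permutations = 0` is the aggregation default; 999 gives
permutation p-values). The partition is verified against the classical
coordinate ANOVA decomposition for Euclidean distances (1e-10) and
against scikit-bio's PERMANOVA pseudo-F.

Distances per representation: log-Pearson (1 − Pearson correlation of
log profiles, natural log, with a half-minimum offset when zeros are
present) and Bray–Curtis for absolute, relative, TMM and DESeq-style
data; for CLR data, the correlation of the CLR values themselves
(already log-scale) and the Aitchison distance (Euclidean on CLR).

## Aggregation

Scenario-level means over iterations come first; the experiment mean
weighs the 30 scenarios equally, the maximum is over scenario means, and
fold changes divide each transformation's mean rate by the
absolute-data mean. Per-iteration RNGs are seeded by
`(master seed, experiment, scenario index, iteration)`, so any cell is
independently reproducible and results merge identically regardless of
execution order.

## Problem sizes

Defaults reproduce the full design: 30 scenarios × 100 iterations per
experiment. The test suite exercises the same full grid at 40 iterations
per scenario — the grid average over 30 scenarios dominates Monte-Carlo
error, leaving scenario-mean summaries stable to well under 0.01 at that
depth — and the reproduction script (`scripts/acceptance.py`) runs the
full 100 iterations for the error-rate summaries with the two
representations they require.

## Open choices, and what the simulation does not show

* **Test-input mode.** Whether the group test compares between-timepoint
  changes, post-only values, or pooled timepoints is not uniquely
  determined by the benchmark's description. We compared the
  reconstructions empirically: the change mode is the only one
  consistent with the error tables' structure (post-only roughly doubles
  the ground-truth miss rates and halves the relative-abundance false
  positives); log-ratio vs plain-difference changes are nearly
  indistinguishable after a rank test, and log-ratio is the default.
* **Rate denominators.** The half-class convention above was chosen
  because the 0.500 saturation of the error tables identifies it
  uniquely; the total-taxa alternative would let maxima reach 0.75 at
  75% response.
* **Ground-truth error levels.** Under this generative model,
  non-responding taxa are exchangeable between arms in absolute data, so
  ground-truth false positives arise only from BH's adaptivity (the
  step-up threshold rises when many true effects are rejected); that
  caps the ground-truth FP rate near 4–5% in the worst (75%-response)
  scenarios. Similarly, a single ±25% uniform noise multiplier makes a
  0.5× effect (×1.5) nearly always detectable — the change supports
  barely overlap — so ground-truth misses concentrate almost entirely in
  the 0.1× row. Reported error levels on *real* absolute-abundance data
  with additional measurement noise will be higher.
* **Correlation-distance saturation.** 1 − Pearson(log profiles) is
  invariant to a common per-sample shift, so in the unidirectional
  regime its mean R² is not monotone in the proportion responding: as
  the responding fraction approaches one with a common direction, the
  treatment effect approaches a per-sample intercept and the distance
  stops seeing it (the proportion margin dips at 75%). Bray–Curtis and
  the bidirectional regime are monotone in both grid margins.
* **What passing tests do not show.** The generator has no sparsity, no
  phylogenetic structure, no sequencing error, and its noise law is
  known exactly; conclusions about the *relative* behaviour of the
  normalizations transfer to real data only to the extent that those
  features do not interact with compositionality.
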