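# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Conceptual-structure statistics

A property-norm set is a long table of (concept, feature, production
frequency, taxonomic flag) with production frequency ≥ 1 and unique
(concept, feature) pairs.  From it:

* **Feature distinctiveness** `d = 1/k`, `k` = number of concepts listing
  the feature.  `k ≤ 2` → *distinguishing*, `k > 2` → *shared*.
* **Sharedness bands**: shared, non-taxonomic features are median-split on
  `d`; features with `d` at or below the median (the more widely shared
  half) are assigned *high S*, the rest *low S*.  Ties at the median go to
  high S — a deterministic rule that keeps band sizes closest to equal
  when many features carry the same `k`.  On other norm sets the split
  point differs; the module always computes its own median.
* **Correlational strength**: for every unordered pair of shared,
  non-taxonomic features, the Pearson correlation between their
  production-frequency vectors across *all* concepts, with 0 where a
  feature is absent.  Significance uses the two-sided p-value from
  `t = r·sqrt((N−2)/(1−r²))` with `N` = number of concepts, at a
  configurable level (default α = .05).  Because the underlying construct
  is feature co-occurrence, only positive correlations count as
  significant by default (`positive_only`, configurable).  Pairs with a
  constant vector have undefined `r` and are never significant.
* **Concept statistics**: NOF (count of non-taxonomic features), mean
  distinctiveness (mean of member features' `d`), and mean correlational
  strength (mean `r` over the significantly correlated shared pairs with
  both members inside the concept).  The natural log of the latter is the
  regression predictor; concepts with no significant pair get a missing
  value and are excluded (with a warning) from analyses that use it,
  rather than imputed.  Taxonomic features (category labels such as *is an
  animal*) are excluded from all three statistics, though they do receive
  network nodes.

## The attractor network

Architecture: an input layer (default 30 nodes) fully connected to a
recurrently connected semantic layer with one logistic node per feature in
the norms (semantic–semantic weights are a full matrix including self
connections, plus per-node biases).  Per tick,

    e_n(t) = Σ_k w_kn u_k(t) + Σ_m v_mn a_m(t−1) + b_n
    x_n(t) = c·e_n(t) + (1−c)·x_n(t−1)
    a_n(t) = σ(x_n(t))

The integration rate `c` (default 0.2; the studied grid is 0.16/0.2/0.24)
controls how quickly a node tracks its external input.

**Staged input.** At tick `t`, input nodes `1..min(t, t_input)` are
clamped to their word-form values and the remaining input nodes to a
baseline (default 0, i.e. silence; a configurable baseline of 0.5 emulates
fully uncommitted evidence).  With the zero baseline, the reveal of a node
whose pattern value is 0 is observationally silent — documented rather
than avoided, since silence and "not yet heard" are genuinely
indistinguishable in this code.  The full pattern stays clamped from tick
`t_input` (word offset, default 30) to `t_total` (default 50).

**Initialization.** Weights and biases start uniform in [0, 0.05].  The
random initial state in [0, 0.1] is assigned to the *integrated inputs*
`x_n(0)`, so initial activations sit just above the logistic midpoint and
are washed out geometrically by the `(1−c)` factor; this reading is
forced by the limit behaviour of the recurrence (with all-zero weights,
`x` decays to 0 and activation to σ(0) = 0.5).

**Training.** Continuous recurrent backpropagation through time on the
binary cross-entropy between activations and the concept's binary feature
targets (production frequency ≥ 1; a frequency-weighted option exists),
summed over semantic nodes and over **all** `t_total` ticks and averaged
over items.  The all-tick loss presses the network to activate features
consistent with the accumulating input as early as possible — the
cohort-model principle the simulation exists to capture.  The gradient is
propagated through the unrolled recurrence including the c-weighted
averaging; a finite-difference oracle in the test suite verifies it to
< 1e-4 relative error.  Cross-entropy is epsilon-clipped at 1e-7.

Optimisation is full-batch gradient descent with momentum 0.9 and learning
rate 0.01 for 2000 epochs — chosen once for stable convergence to a
settled attractor regime on the desk-scale synthetic norms (final
activations near their targets; mean per-item loss falling two orders of
magnitude).  Larger learning rates destabilise the late-tick attractors.
The initial integrated inputs are re-randomized from the seeded generator
every epoch, so the learned attractors are robust to the randomized starts
used at evaluation.  Non-finite loss aborts with a diagnostic.  Everything
is deterministic given the configuration seed.

**Evaluation.** Five forward passes with independently randomized initial
states (weights fixed; both activations and integrated inputs are
re-drawn, the same quantities randomized at training), averaged
element-wise.  The ensemble (`run_grid`) trains one model per pattern set
× `c` cell with a deterministically derived seed per cell; the full
30 × 3 grid is supported (and enumerable via dry-run) but long-running,
so the desk-scale default is 3 pattern sets.

## Simulation analyses

* **Band trajectories** pool feature instances (concept × member feature)
  by band (D / low S / high S; taxonomic excluded) per tick; the
  *non-target* band pools, per item, all features outside the item's
  concept.
* **Band contrasts**: two-sample t-tests per tick for the three pairwise
  band contrasts, with the dispersion taken across ensemble instances
  (trained models), at the Bonferroni-corrected level
  α/(t_total × 3) = .05/150 for the defaults.  The choice of a two-sample
  t-test across ensemble instances is a documented assumption.
* **Per-tick regression**: the dependent variable is the mean activation
  of each concept's non-taxonomic target features at tick `t` (run
  averaged); predictors default to mean distinctiveness and log mean
  correlational strength (NOF available behind a flag — the lexical and
  phonological covariates of the behavioral analysis have no meaning for
  the network).  DV and predictors are z-scored, so coefficients are
  standardized betas; with an ensemble, the reported beta is the
  across-member mean and its standard error the across-member SE.  A
  zero-variance predictor yields an undefined (NaN) beta, never 0.
  Helper functions provide a centered moving average (window 5) and a
  sign-change count for reading the time course of the coefficients.

## Behavioral analyses

* **Inverse transform** 1/RT (so facilitation = positive coefficient on
  speed); the harmonic mean of RTs is the RT whose speed equals the mean
  speed.  Phoneme rate = phonemes per ms of stimulus duration.
* **Condition index**: columns mean-centered and scaled to unit length,
  index = ratio of extreme singular values; rank deficiency reports ∞.
* **Per-subject (random) regression**: OLS of inverse RT on the item
  predictors plus the session covariates present in the data (trial order,
  previous-response same, previous-response error, previous-trial speed;
  droppable by flag), correct responses only, predictors standardized over
  the full analyzed set so coefficients are comparable across subjects.
  Subjects with fewer than `n_predictors + 10` rows are excluded with a
  warning.
* **Speed sensitivity**: Pearson correlation of each predictor's
  per-subject coefficients with subject mean inverse RT, with the
  parametric two-sided p.  Zero-variance input is an error, not r = 0.
* **Bootstrap CI**: subjects resampled with replacement (default
  B = 10,000), bias-corrected (BC, median-bias without acceleration —
  the plain "bias-corrected" variant; BCa was considered and left out as
  an unneeded degree of freedom).  Degenerate resamples are redrawn and
  capped.
* **Permutation contrast**: observed statistic |r_A| − |r_B| (magnitudes
  in the hypothesized direction; a signed variant is available by flag),
  null built by permuting the subject speed vector jointly against both
  coefficient vectors (preserving their mutual dependence), one-sided
  p = (#{null ≥ observed} + 1)/(P + 1).

## Synthetic generators

All generators are pure functions of (config, seed).

* **Norms**: concepts come in equal-size categories.  Each concept lists
  10–14 features: a binomial share (p = 0.25) unique to it, the rest drawn
  from a per-category pool of 14 (features shared by several category
  members — moderately shared, mutually correlated through co-occurrence)
  and from a cross-category pool of 10 (widely shared features), roughly
  70/30.  One taxonomic category-label feature is attached to every
  concept.  Production frequencies are 1 + Poisson(5) draws — a stated
  modelling choice, as published norms report only integer counts ≥ 1
  with a right-skewed distribution.  The defaults yield ~250–280
  features for 60 concepts with clear gradients in both concept
  statistics and a pairwise predictor correlation well below 0.5.
* **Word forms**: distinct uniformly sampled 3-of-30 binary patterns.
* **Behavioral data**: per subject, speed (inverse RT, 1/s) = base speed
  (1000/800 ms) + a N(0, 0.12) subject offset + planted linear effects of
  the z-scored item predictors + N(0, 0.12) residual noise, with the
  correlational-strength coefficient varying linearly with the subject's
  overall speed (slope −0.06 per SD of subject speed: slower subjects get
  a larger facilitatory effect, the structure the speed-sensitivity
  analysis targets).  The default planted effects are
  mean_distinctiveness −0.05, mean_cs_log +0.02 (at mean speed), NOF
  +0.02.  34 subjects by default.  Session covariates are emitted with
  zero true effect, so their estimated coefficients are pure noise — a
  testable property.  Reaction times are back-transformed and resampled
  in the (practically unreachable) event of a non-positive speed.

What the generators do **not** emulate: real norms' feature-type
structure, homophone or familiarity effects, non-word foils, error
processes, and the long-tailed RT distributions of real subjects.
Passing tests therefore demonstrate that the machinery recovers structure
of the assumed form, not that real data contain that structure.

## Problem sizes and determinism

The package's desk-scale defaults — 60 concepts in 6 categories
(~250–280 feature nodes), 3 pattern sets × one or three `c` values, 5
evaluation runs, 34 subjects — are the conditions all end-to-end tests
use; the qualitative dynamics suite trains 3 seeds at c = 0.2
(~3 minutes per model on one core).  The full-scale setting (517
concepts × 2,341 nodes × 90 models) is supported by the same code paths
but takes hours.  Every stochastic stage takes its seed from the
configuration (the pipeline derives per-stage seeds from one global seed
and records them in the run manifest), so reruns reproduce outputs
bit for bit.

## Known limitations

* The update regime, learning rate, epoch count and presence of trainable
  biases are not dictated by the modelled phenomenon; they are package
  defaults chosen for stable desk-scale convergence and are all exposed
  in `NetworkConfig`.
* The late-tick reversal (distinguishing features overtaking shared ones)
  emerges only once training has pushed the attractors close to their
  targets; undertrained networks show the early shared-feature advantage
  but not the reversal.
* With the zero input baseline, early input reveals carry information
  only through pattern-1 nodes; the alternative baseline changes the
  early dynamics quantitatively but not the qualitative pattern.
* Mixed-effects modelling of trial-level RTs (random slopes, MCMC
  p-values, model selection) is deliberately out of scope; the
  per-subject random-regression route covers the speed-sensitivity
  questions the package addresses.
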