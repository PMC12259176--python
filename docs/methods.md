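# Methods

## Generative model

Each synthetic unit carries a private random ranking of the image set (its
tuning curve) and a set of scalar parameters drawn from a region
configuration. For image *i* with memorability *m* and tuning rank
*x = rank_u(i)*, the expected evoked rate on the novel presentation is

    evoked_novel = A · exp(−α·x) · (1 + g·(m − 0.5))

with peak amplitude `A` (spikes/s), selectivity `α` (per rank), and
memorability gain `g` (dimensionless; centred at m = 0.5 so that a
symmetric score distribution leaves the mean rate invariant to `g`). On the
repeated presentation, from the unit's memory onset onward, the evoked rate
is multiplied by

    s_b^(1 + κ·(m − 0.5)) · (evoked_novel / ref)^(e − 1)

where `s_b ∈ (0, 1]` is the suppression base (fraction of the evoked rate
kept), `e ≥ 1` the suppression exponent (1 = proportional suppression,
> 1 = supra-proportional: vigorous responses lose a larger fraction),
`κ` the memorability–suppression coupling (suppression deepens with
memorability even at zero gain), and `ref` the unit's mean novel evoked
rate at m = 0.5 (a per-unit normalisation that keeps `e` dimensionless and
makes the population log-log scaling slope equal `e` in the clean power-law
regime). The factor is clipped to [0, 1]; negative pre-floor rates (possible
for strongly negative gains) are clipped to zero and counted.

Spike counts are Poisson per 20 ms bin over a −500…+800 ms trial window:
baseline rate before the unit's response latency, baseline + evoked from
latency to 600 ms, with the suppression factor applied from the memory
onset. All randomness derives from one root seed through named sub-streams
(images, sequence, units, spikes, behavior, assembly, folds, permutations,
bootstraps), so e.g. changing the unit count never perturbs the behavioral
draws.

### Region configurations

*ITC-like* (high-level visual cortex): baseline Γ(mean 5 sp/s), peak
Γ(mean 20 sp/s), selectivity U(0.01, 0.03), gain N(0.8, 0.8), suppression
base N(0.80, 0.12), exponent 1.2, coupling N(1.6, 1.0), latency
N(100, 15) ms, memory onset N(150, 25) ms. The wide gain and coupling
spreads are deliberate: the rotated-decoder scheme requires meaningful
heterogeneity in unit-level memory vs. memorability sensitivity — with
homogeneous gain the two population directions are collinear and no
rotation can separate them. These values were calibrated once, against the
study conditions the analyses assume: ~7.6% mean GMFR suppression and a
strongly positive memorability–GMFR correlation at 200-image sessions, an
RS–MB plane angle near 51°, and a best-PQ rotation slightly past orthogonal
to the MB axis.

*HC-like* (hippocampus): baseline Γ(3), peak Γ(8), gain N(0, 0.1) —
population vigor does not track memorability — suppression base
N(0.855, 0.04), exponent 1, coupling 0.2, giving ~4.6% suppression that
still increases with memorability (the isolated memory signal is larger
for more memorable images) while remaining statistically negligible as a
vigor slope at realistic noise levels.

### Trial sequences

Every image appears exactly twice, novel then repeated. Target n-back
levels (default 1, 2, 4, 8, 32, 48, 64, 192) receive a uniform core count
with half frequency at the two extremes; targets are allocated
stochastically but realized exactly. Gaps inserted only to keep the
sequence contiguous are emitted with `on_target=False` and excluded from
analysis, mirroring the filler repeats of the behavioral task.

### Behavior

Choices follow a logistic model: P(correct | repeated) =
expit(1.8 + 4.0·(m − 0.5) − 0.3·(log₂ n-back − 2)), P(correct | novel) =
expit(2.5 − 0.5·(m − 0.5)). Defaults give ~85% mean repeated-trial accuracy
spanning roughly 55–97% over the memorability range — the regime of trained
macaques on this task — with hit rate rising in memorability and falling in
n-back, and a slight memorability-driven false-alarm increase on novel
trials.

## Screening and pseudopopulations

Units are included when a paired two-sided t-test of post-stimulus
(50–350 ms) vs. pre-stimulus (−300–0 ms) rates across all trials gives
p < 0.10; degenerate units (zero-variance differences) get p = 1 when flat
and p = 0 when shifted by a constant. Sessions fail the stability screen if
mean baseline rate in the first fifth vs. last fifth of trials differs by
more than 2-fold, or if baselines preceding novel vs. repeated images
differ (t-test, p < 0.01, −500–0 ms).

Pseudopopulations concatenate units across sessions. Image pairs are
stratified by memorability bin (default 10 equal-width bins on [0, 1]) and
exact n-back level; each stratum contributes the minimum eligible pair
count across sessions, with excess pairs dropped uniformly at random
(seeded). Every (unit, pseudoimage) cell holds one real image's novel and
repeated counts; a pseudoimage's representative memorability is the mean
of its contributors. `shuffle_alignment` permutes, within each unit
independently, the image-to-pseudoimage assignment (pairs travel
together), destroying across-unit memorability alignment while preserving
each unit's marginal count distributions exactly.

## Vigor statistics

GMFR is the across-unit mean firing rate per pseudoimage and presentation
(spikes/s in a spike-count window; default 300–500 ms, 100–500 ms for the
plane analyses). Pearson correlations use the exact t-transform p-value
(df = n − 2). The slope-difference test pools the two tables' points,
permutes the region labels without replacement (default 10,000 times), and
reports the two-sided proportion of null |Δβ| at least as large as
observed, with the observed statistic included in the null set
(p ≥ 1/(n_perm + 1)).

The suppression-scaling exponent is the slope of log(repeated GMFR −
baseline) on log(novel GMFR − baseline) across pseudoimages. Because both
axes carry comparable Poisson measurement noise, the default estimator is
the standardised-major-axis slope (sign(r)·sd_y/sd_x), the standard choice
for allometric log-log scaling; ordinary least squares is available but
attenuated under errors-in-variables. Passing the pre-stimulus baseline
makes the exponent describe evoked-rate scaling; without subtraction the
shared baseline compresses the slope toward values below 1 even for
proportional suppression. Confidence intervals are percentile bootstraps
over pseudoimages. Note that the stock ITC-like configuration is *not* a
clean power law (the κ coupling adds rate-independent deepening, the
factor clip and latency/onset mixture flatten the tail), so the exponent
it yields is a population summary, not a recovery of `e`; recovery is
exact in the power-law regime (constant s_b away from the clip, κ = 0,
onset at the window start).

## Classifiers

d′ per unit is (mean novel − mean repeated)/pooled SD with pooled SD
= sqrt((var_n + var_r)/2); zero pooled SD gives d′ = 0. The FLD weight is
the class-mean difference divided by the two-condition average variance
(diagonal covariance only; variances floored at 10⁻⁶ of the mean variance;
zero-variance units get weight 0), which is d′ weighting up to the variance
convention and agrees exactly with diagonal-whitened nearest-class-mean
classification. The RS classifier weights every unit equally — a pure
population-vigor threshold. Ties f(x) = 0 classify as repeated (needed for
integer counts; measure-zero otherwise). Cross-validation keeps each
pseudoimage's pair in one fold, stratifies folds by memorability bin
(default 10 folds), and reports per-fold accuracies. The ranked-FLD curve
re-ranks and re-fits within each training fold before removing a fraction
of units from either end of the signed-weight ranking.

## Tuning fits and thresholding

The per-unit model y(x; M) = A_M·e^(−αx) (expected spike *count* in the
100–500 ms window; separate amplitudes for novel/repeated, shared α) is fit
by Poisson maximum likelihood. For fixed α the optimal amplitudes are
closed-form, A_M = Σk_M / Σe^(−αx), so the fit is a bounded 1-D
profile-likelihood optimization over α ∈ [0, 2] (xatol 10⁻¹⁰); this is
exact in the inner maximization and needs no restarts. Rates are floored at
10⁻⁸ inside the log-likelihood; all-zero units are flagged unconverged
with A = 0. Image ranks come from the observed novel/repeated-averaged
counts, ties broken by image order.

Thresholding at fraction N modifies ranks ≥ floor((1 − N)·n_images): both
curves are replaced by the repeated-curve value *at the cutoff rank* (flat
tail; the tail then carries neither selectivity nor memory). The
alternative reading — each rank keeps its own repeated value — is
implemented behind `mode="per_rank"`. The threshold sweep synthesizes a
Poisson population per fraction from a shared spike stream (so fraction 0
reproduces the unthresholded population exactly at the same seed) and
reports the repeated-condition memorability correlation with bootstrap CI
and cross-validated FLD accuracy.

## The RS–MB plane

The MB axis is a prototype classifier: mean response to the
top-half-memorability training pseudoimages minus the bottom half
(presentations pooled by default; novel-only and repeated-only behind a
flag). γ is the angle between the normalized all-ones axis and the MB
axis. The rotated family W(θ) = (cos θ − cot γ·sin θ)·1̂ +
(csc γ·sin θ)·ŵ_MB is unit norm with angle θ to the RS axis;
W(γ ± 90°)·ŵ_MB = 0 is the memorability-blind direction.

The θ sweep's default grid is (−90°, 90°] in 1° steps: every line of the
plane once, each with the polarity nearest the RS axis. The sweep then
traverses MB, RS and the memorability-blind direction in a single arc —
predictions begin misaligned with behavior, become aligned, and end
misaligned in the opposite direction. The sign-flipped half-turn (θ beyond
90°) contains only decoders whose memory readout is inverted
(below-chance accuracy); admitting them lets saturated, flat accuracy
curves spuriously match shallow behavioral slopes, so they are excluded by
default (a user grid may include them; a warning fires for grids spanning
less than 180°). Per fold, the MB prototype, γ, and the midpoint bias are
recomputed from training data for every θ; held-out pseudoimages are
classified and per-quartile accuracies aggregated across folds.

Prediction quality fits least-squares lines to per-quartile accuracy
(fractions in [0, 1]) against quartile-mean memorability for behavior and
prediction, per condition; Δθ is the absolute difference of the slope
angles, reflected by 180° − Δθ when above 90° (slopes 180° apart are
equivalent); PQ = 1 − Δθ/90, averaged over novel and repeated. Keeping
accuracies and memorability both on [0, 1] scales makes the slope-angle
geometry meaningful (steep-saturated and shallow slopes are
distinguished). Best-PQ ties break toward orthogonality to the MB axis.
Plane projections use an orthonormal in-plane basis (Gram–Schmidt, first
axis along RS, view rotated 45° for display) so in-plane distances — and
the 1-SD covariance ellipses per novelty × memorability-quartile group —
are faithful; an isotropic cloud projects to a circle. Behavior
rescaling fits the single multiplicative factor c = Σpb/Σp² and clamps
rescaled predictions above 100% to 100 with flags.

## Problem sizes in the test battery

The automated tests run at desk scale, chosen to keep each property
measurable in minutes: unit tests use 25–150 units and 80–160 images;
the dissociation battery uses 200-unit ITC-like and 80-unit HC-like
sessions with 280 images over 20 seeds; exponent recovery uses 500 units
and 200 images per seed; the paradox/resolution battery uses 600 units and
400 images over 20 seeds (roughly the pooled-session scale of the analyses
the pipeline reproduces). Permutation and bootstrap counts are reduced in
tests (1,000/200) relative to the analysis defaults (10,000).

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: exactly-twice
sequences with controlled n-back gaps, memorability-graded vigor and
suppression, Poisson count noise, heterogeneous selectivity and memory
sensitivity, and behavior whose accuracy rises with memorability on
repeats. It does not model biophysics, spike-train temporal structure
beyond inhomogeneous Poisson rates, eye movements, reward or satiation
drifts, across-trial adaptation beyond the single repetition, correlated
noise between simultaneously recorded units, or the image-computable
origin of memorability (scores are inputs). Passing tests therefore
establish the correctness and calibration of the analysis chain on data
with this structure — not that real recordings satisfy the model.

## Known limitations

- The suppression-scaling exponent is this package's operationalization of
  supra-proportionality; quantitative comparisons to other formulations of
  "suppression grows with vigor" require care about baselines and windows.
- The pseudopopulation's minimum-per-stratum rule discards data when
  sessions are unbalanced; no imputation is attempted.
- The population-size extrapolation behind behavior comparison is the
  single multiplicative rescaling only, not an explicit neuron-count
  simulation.
- Anatomical/hardware session criteria are metadata flags, not computed.
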