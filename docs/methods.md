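# Methods

This note documents the models and procedures implemented in `chronobiome`,
the defaults chosen where the methodology left a genuine choice, and what the
synthetic benchmarks do and do not establish.

## Data model

All analyses operate on a `TimeSeriesDataset`: the abundance matrix of one
source (subject/environment) with columns ordered by time stamp and one
observation per time point (tied time stamps are rejected). Time stamps are
treated as **ordinal positions** by every algorithm — DTW, Granger
regressions and the ADF test all assume equal spacing — and a warning is
raised when the recorded spacing is non-uniform. Resampling irregular series
onto a uniform grid is deliberately out of scope; users with strongly
irregular designs should interpolate upstream.

## Normalization

Two routes are provided. *Relative* normalization scales each sample to
proportions; all-zero samples are left as zeros with a warning.
*Rarefaction* draws a without-replacement subsample of exactly `depth` reads
per sample (a multivariate-hypergeometric draw via `numpy`'s generator), so
every surviving column sums exactly to the depth; shallower samples are
dropped, and the seed is a required, recorded parameter. Rarefaction curves
report the Monte-Carlo mean richness over replicates (default 10,
configurable) per depth; at full depth the curve equals observed richness
exactly, and the unit test checks the curve against the closed-form
hypergeometric expectation `E[S] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d))`.

Both normalizations yield compositional data; fluctuations in one dominant
taxon induce apparent fluctuations elsewhere. Downstream stationarity and
causality calls on relative abundances inherit this caveat and the run
metadata records which normalization produced the analysed matrix.

## Diversity and occupancy classes

Richness is the count of taxa with abundance > 0 per time point; diversity is
the Shannon index `H = −Σ pᵢ ln pᵢ` (natural log), computed over the sample's
proportions so counts and proportions give identical values.

Occupancy classes formalize presence patterns over the timeline with
presence defined as abundance strictly greater than zero (no minimum-count
filter):

* **core** — present at every time point;
* **persistent** — prevalence > 0.20 and longest consecutive presence run
  ≥ 0.90 of all presence points;
* **transient** — prevalence ≥ 0.60 and longest run ≤ 0.75 of presences;
* **other** — anything else.

"Fraction of observations that are consecutive" is formalized as
*longest run ÷ number of presence points*. The persistent and transient
rules are not mutually exclusive a priori, so calls are resolved with
precedence core > persistent > transient; a taxon with prevalence 0.65 and
run fraction 0.8 satisfies neither rule and is classed `other`. All four
thresholds are user-overridable.

## Stationarity screening

Each taxon's series is tested with the augmented Dickey–Fuller regression;
the null hypothesis is a unit root (shocks persist; the series drifts), the
alternative stationarity. Defaults: deterministic term = constant only (no
trend — abundance series have no a-priori linear trend; `constant_trend` is
available), lag order selected by AIC up to `trunc((n−1)^{1/3})`, stationary
call when p < α = 0.05. A constant series is reported *untestable*, never
stationary. Raw p-values drive the calls — the screen is exploratory, and
flags feed the network overlay — but a BH-adjusted column is emitted for
users who want family-wise control. Series are tested on whatever scale the
user's preprocessing produced (recorded in the report header); `--log` is
available because strongly right-skewed abundance series are closer to the
test's linear-Gaussian assumptions after log transform.

## Temporal-shape distances

`dtw_distance` is the standard dynamic program with local cost `|xᵢ − yⱼ|`,
unweighted match/insert/delete steps, evaluated only inside a Sakoe–Chiba
band of half-width `band` (default `max(10, ⌈0.1·T⌉)`, the classical 10%
convention). The implementation is checked against an exhaustive
all-warping-paths oracle on short series.

The bounded variant `time_dtw_distance` makes alignments comparable across
pairs:

1. z-normalise each series with the population standard deviation
   (constant series are rejected by name, not imputed);
2. compute the banded DTW cost between the normalised series;
3. divide by the mean of each series' sum of absolute differences from its
   mirror image; after z-normalisation the mirror is the reflection `−s`, so
   the normaliser is `(2Σ|x̃| + 2Σ|ỹ|)/2` — the pointwise cost of a series
   against its own maximally dissimilar counterpart;
4. clip at 1 (warping can very occasionally push the ratio past 1 for
   pathological pairs; clipping events are the only information lost).

The value is 0 iff the z-normalised shapes align perfectly and reaches 1 for
a shape against its reflection when warping cannot help (e.g. two-point
series); with room to warp, even a series and its exact mirror can align
more cheaply than the normaliser (the alternating 4-point series scores
0.5), which is a property of warping, not an artifact. The DTW cost is *not*
divided by path length before normalisation; this choice is recorded in run
metadata. Consequences of z-normalisation: the distance is invariant to
positive affine transforms of either series.

Pearson correlation (distance `1 − r`) is available as the classical
alternative; hierarchical clustering uses average linkage by default on
either matrix, with Newick export of the dendrogram.

## Granger-causality networks

*Pairwise*: for an ordered taxon pair (A → B), compare the restricted
regression of `B_t` on its own `lag` past values (plus intercept) with the
unrestricted one that adds A's past, by the nested-model F-test. Default lag
is 1 (short series dominate this field), user-settable. P-values are
BH-corrected across all ordered pairs; both raw and adjusted values are
exported and the threshold applies to the adjusted one by default.

*Granger-Lasso*: each taxon's present is regressed on the lag-stacked past
of all taxa, z-standardised so the shared L1 penalty is scale-fair. The
penalty is selected per target by BIC (LARS path), and surviving
coefficients are thresholded at 0.1 standardised units — the thresholded
Lasso. The prediction-optimal (cross-validated) penalty was evaluated and
retains many small spurious coefficients, which is the known behaviour of
CV-min Lasso in support-recovery settings; BIC plus thresholding recovers
planted supports reliably at the benchmark sizes. A fixed `penalty` can be
passed to bypass selection (0 reduces to OLS).

*Intersection* keeps edges found by both methods, trading recall for
precision. Node attributes carry the stationarity flags so non-stationary
taxa can be highlighted on the exported GraphML. Series are **not**
differenced before testing — stationarity is overlaid rather than enforced,
and the interpretation caveat (Granger edges are predictive, possibly
confounded, not mechanistic) applies especially to edges involving
non-stationary taxa.

## Community states

Each time-point column is scaled to a probability distribution and pairwise
dissimilarity is the Jensen–Shannon divergence with natural logarithm
(`JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M)`, `M = (P+Q)/2`), bounded by `ln 2`; the
natural log keeps it on the same scale as the Shannon index. The JSD matrix
is clustered by PAM K-medoids: a deterministic greedy BUILD initialisation
followed by SWAP iterations whose objective (total distance to medoids) is
non-increasing; the seed only breaks exact ties. `k` is a user choice
(default 2); a silhouette table over k = 2..6 is available to guide it.
Driver taxa are ranked by the spread of per-state mean relative abundance
(max − min across states), and taxa are additionally ordered by hierarchical
clustering on the bounded DTW distance for heatmap display.

## Differential abundance

Two non-overlapping inclusive index windows (or contiguous condition labels)
are compared per taxon: window means, fold change
`log₂(mean₂ + pc) − log₂(mean₁ + pc)` with pseudocount = half the smallest
nonzero abundance in the dataset (computed as a difference of logs so that
swapping the windows negates it exactly in floating point), and a two-sided
Wilcoxon rank-sum test — exact null enumeration for tie-free windows of ≤ 20
points, normal approximation with tie/continuity correction otherwise; fully
tied data return p = 1. BH correction across taxa; records are sorted by
|fold change|, and taxa present in window 1 but absent throughout window 2
carry an `eliminated` flag.

## Synthetic benchmarks

The generators plant exactly the structure each workflow estimates: a stable
VAR(1) with chosen coefficient matrix (causal edges), white-noise vs
random-walk taxa (unit roots), Dirichlet draws around two compositions
following a block pattern (community states, concentration 200 by default —
tight, clearly separated states), phase-shifted sine groups (temporal
shapes), and log-normal series with planted 4-fold location shifts
(differential abundance; σ = 0.4 log-noise and 15 points per window make the
shift ≈ 3.5 noise SDs, a clearly detectable but not degenerate effect).
Latent Gaussian paths are exponentiated to strictly positive log-normal
abundances rather than truncated, so no spurious zeros perturb occupancy
logic; analyses that assume linear dynamics should therefore run on the log
scale (`--log`), which restores the latent process up to an affine map that
F-tests and the ADF regression are invariant to.

Benchmark sizes (200 time points for single-series tests, 300 for the
10-taxon Lasso recovery, 60 points for two-state recovery, 100–500
replicates per rate) keep the full suite in the tens of seconds while the
binomial error on every estimated rate stays well inside the asserted
margins.

These benchmarks establish *correctness of the estimators under their own
assumptions* — linear dynamics, independent Gaussian innovations, clean
compositional states. Real microbiome series add sequencing noise,
zero-inflation, compositional coupling and irregular sampling, none of which
the generators emulate; passing benchmarks therefore validate the machinery,
not the biological interpretability of any particular dataset's output.

## Numerical and degenerate-input choices

* Quartile segregation ranks taxa by mean abundance over time (simple,
  scale-separating); ties break by label so output is deterministic; < 4
  taxa fall back to a single group with a warning.
* Log scaling uses base 10 with pseudocount 1 for counts and half the
  smallest nonzero value for proportions.
* Moving averages use a trailing window (no look-ahead leakage).
* All-zero samples: relative normalization leaves them (warning), Shannon
  returns NaN (warning), JSD raises (composition undefined).
* All stochastic steps (rarefaction, simulations, K-medoid tie-breaks) take
  explicit seeds; CLI runs record every parameter in `run_metadata.txt` and
  re-runs are byte-identical.
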