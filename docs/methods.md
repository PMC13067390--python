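# Methods

This note documents the models, conventions and numerical choices behind
`dynfc`, what the synthetic cohort generator does and does not emulate, and
the design decisions taken where more than one convention is defensible.

## Connectivity

Static functional connectivity is the Fisher z-transform of the pairwise
Pearson correlation of ROI time courses over the full scan. Correlations
are clipped to ±(1 − 10⁻⁷) before `atanh` so that degenerate inputs
(duplicated or perfectly anti-correlated columns, common in synthetic and
edge-case data) map to a finite ceiling of ≈ ±8.4 rather than ±∞, which
would otherwise poison the cosine geometry of the downstream clustering.
The diagonal is fixed at 0; self-connections are excluded from
vectorization and from all graph metrics.

Dynamic FC uses a rectangular (untapered) sliding window stepped one TR at
a time; each window's correlation demeans within the window only (implicit
in Pearson r). Defaults follow a ~39.6 s window: 55 TRs at TR = 0.720 s
(40 TRs at TR = 0.987 s gives the matched 39.48 s variant). No global-signal
regression, filtering, or other preprocessing is applied — the package
starts from already-preprocessed parcellated series.

Motion QC: a subject fails when strictly more than 7.5% of frames have
framewise displacement ≥ 0.5 mm. The boundary fraction passes. The median
FD is reported for group-level motion comparisons.

## Graph metrics

FC matrices are converted to graphs by zeroing negative z-values and
dividing by the matrix maximum, so weights lie in [0, 1]. Rationale: the
standard weighted definitions of both metrics assume nonnegative weights,
and max-normalization bounds inverse edge lengths by 1 so global efficiency
lands in [0, 1] — the magnitude range on which these parameters are usually
reported (≈ 0.36–0.45 for efficiency on real cohorts). The choice is
recorded in output metadata and the conversion is a separate, testable step.

Global efficiency is the mean over ordered node pairs of `1/d(i,j)` with
edge length `1/weight` (Dijkstra shortest paths); disconnected pairs
contribute 0. Modularity is Newman's weighted Q at resolution γ = 1,
maximized over 20 seeded Louvain restarts; ties between restarts break
toward the lexicographically smallest canonical partition, making the
result deterministic given the seed. No density thresholding or
sparsification is applied. On 6–8-node graphs the restart scheme reaches
the exhaustively enumerated optimum (tested over all set partitions).

## Brain states

All passing subjects' window matrices are vectorized (upper triangle) and
pooled into one group-level clustering problem — a single shared two-state
model, not per-subject models. k-means with cosine distance is implemented
as spherical k-means: vectors are L2-normalized, assignment maximizes the
dot product with unit centroids, and the centroid update is
mean-then-renormalize (the exact minimizer of summed cosine distance for a
fixed partition). Initialization is k-means++ adapted to cosine distance;
the best of `n_init` runs by cosine inertia wins (pipeline default 20;
100 for small pools where the exhaustive optimum is verified). Empty
clusters re-seed at the worst-fit point. Convergence tolerance 10⁻⁶ on the
inertia, max 300 iterations.

Returned centroids are the *un-normalized* means of the assigned raw
vectors, keeping them on the Fisher-z scale for interpretation. Labeling:
the centroid whose matrix has the higher global efficiency is the
integrated state I; a consistency check warns if it does not also have the
lower modularity (efficiency decides). An efficiency tie to 10⁻¹² is
rejected as unlabelable. Window assignment is cosine-nearest-centroid with
ties broken toward S.

### Dynamics parameters

With step = 1 TR, each window-label sequence yields:

- **Prev**: percent of windows per state; `Prev_S + Prev_I = 100` exactly.
- **MDT**: mean length of maximal constant runs × TR, in seconds.
  Boundary (censored) runs are *included*: excluding them would discard
  most of the data for subjects with long dwellings. A state never visited
  yields no value, and the subject drops out of that parameter's group
  statistics — this is what makes per-parameter group Ns differ.
- **ITI**: mean gap between consecutive transition indices × TR; absent
  with fewer than two transitions. On long stationary sequences the ITI
  equals the mean interior run duration, i.e. it approximates the mean of
  the MDTs.
- **Var**: 100 × mean cosine distance of a subject's state-assigned window
  vectors from the subject's own mean vector for that state — the extent
  of the within-subject state cloud. The exact published formula for this
  parameter is not specified in the main text of the source literature;
  this definition is the natural one in the cosine geometry of the
  clustering, produces values on the observed scale, and is exposed as a
  strategy option rather than hard-wired.

Time accounting holds exactly: summed over states, MDT × (number of runs)
equals the total sequence duration. Group-level state centroids are the
per-group mean of per-subject elementwise-median window matrices.

## Group statistics

Group 1 is males, group 2 females; all differences read "males − females".
Both the t-test and Mann–Whitney U are run on every parameter, since dwell
and prevalence distributions are typically right-skewed. The
Student-vs-Welch choice defaults to Levene's test at p < 0.05 (explicitly
overridable per comparison, since published tables mix integer and
fractional dfs without stating a rule). One-sided directions are applied
only to the preregistered-hypothesis parameters (females higher `Prev_S`,
`MDT_S`, modularity; males higher `Var_I`, efficiency) and only when the
pipeline is configured for the confirmatory phase; everything else is
two-sided, with no multiple-comparison correction across hypothesis tests.

The Mann–Whitney implementation uses exact enumeration when
`n1·n2 ≤ 400` and the data are tie-free, and the tie-corrected,
continuity-corrected normal approximation otherwise.

Cohen's d uses the pooled SD; its 95% CI uses the normal-approximation
standard error `sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`, which reproduces
published CI bounds to the printed precision; noncentral-t CIs are a
possible extension but are not the default. The Spearman–Brown step-up
`ICC_avg = m·ICC/(1 + (m−1)·ICC)` gives the reliability of an m-session
average (0.5 → 0.667 at m = 2).

## Mediation

Candidates must correlate with both sex and the integration measure
(default mediator: `Prev_I`) at p < α/m, Bonferroni with m = 66. For a
binary group code the correlation test is algebraically the pooled
two-sample t-test; a unit test asserts the equivalence to 10⁻¹⁰.

The path model is fit by OLS with intercepts: `a` from M ~ sex, `(c′, b)`
from Y ~ sex + M, `c` from Y ~ sex. Sex stays on its 1/2 coding; mediator
and outcome are standardized to unit (population) variance on the analysis
sample, once, before fitting — not re-standardized inside bootstrap
resamples. The identity `c = c′ + a·b` holds exactly and is asserted to
10⁻¹⁰. The indirect effect's 95% CI is a percentile bootstrap over
subject resamples (default 5000 draws; percentile rather than BCa is the
minimal reading of a "bootstrap CI" and its coverage is verified
empirically). Resamples with constant sex are redrawn, with an attempt
budget of 100 × n_boot. The bootstrap refits use closed-form centered
normal equations, vectorized across resamples, so 5000 refits cost
milliseconds; the closed form is cross-checked against an independent
least-squares fit in the tests. No correction is applied across the
mediation analyses themselves.

## Synthetic cohorts

The generator stands in for restricted resting-state data. Per subject, a
first-order Markov chain over {segregated, integrated} runs at frame
resolution (initial state from the stationary distribution
`π_S = p_IS/(p_SI + p_IS)`); each frame is an independent draw from a
zero-mean multivariate Gaussian whose correlation matrix depends on the
frame's state. Both state matrices are block-uniform: 1 on the diagonal,
`within_r` inside equal-sized module blocks, `between_r` across blocks,
with closed-form eigenvalue checks rejecting non-PSD settings. Defaults:
10 ROIs in 2 modules, `within_r = 0.6`, `between_r = 0.05` (segregated)
vs `0.45` (integrated) — a well-separated regime in which the two states
are unambiguous at the window level.

Sex-dependent switch probabilities are the planted group difference:
males (p_SI = 0.020, p_IS = 0.011) → π_S ≈ 0.355, females
(p_SI = 0.018, p_IS = 0.0166) → π_S ≈ 0.480. That plants a
~13-percentage-point prevalence difference and mean dwells of roughly half
a minute at TR = 0.720 s, matching the magnitude of reported sex effects in
large resting-state cohorts. Default session length is 300 frames — a
deliberately scaled-down session that keeps replicated whole-pipeline
experiments cheap while leaving several dwell bouts per subject; all
lengths are parameters.

One global seed expands into per-subject `SeedSequence` streams, so any
subject is reproducible in isolation. FD series are folded-normal baseline
motion (~0.14 mm median) with an exact count `round(frac·n)` of planted
spikes ≥ 0.5 mm, to exercise the QC rule on both sides of its boundary.
Behavioral tables contain one planted outcome
`Y = c′·sex + b·M + ε` (defaults a = 0.4, b = 0.3, c′ = 0.2, unit noise)
plus pure-noise columns; in the file-based pipeline the mediator `M` is
each subject's *realized* integrated-state occupancy, so the outcome really
is mediated by the quantity the pipeline later recovers as `Prev_I`.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: BOLD temporal autocorrelation (frames are
i.i.d. within state; real windows are effectively smoother), hemodynamics,
physiological noise, motion artifacts in the signal itself (FD is a
separate scalar series), spatial structure beyond the two-block modular
covariance, and any departure from Gaussianity. Window-level state
mixtures at switch points are present and accepted as realistic blur.
Recovery results on these cohorts validate the *machinery* (clustering,
labeling, sequence metrics, statistics), not effect sizes in real brains.

## Problem sizes and runtime

Replicated experiments use deliberately scaled problem sizes, chosen as
the smallest configurations where the checks are statistically meaningful:
bootstrap coverage uses 500 replicates at n = 500 with 1000 bootstrap
draws each (coverage of a percentile CI depends on n, not on the draw
count, beyond Monte-Carlo noise); sign recovery uses 40 cohorts of 80
subjects, 300 frames, 10 ROIs. Both finish in about a minute each on one
CPU. Exhaustive oracles are bounded by combinatorics: modularity
enumeration at ≤ 8 nodes (4140 partitions), cosine-k-means enumeration at
14 vectors (8192 bipartitions), Mann–Whitney enumeration at ≤ 11
observations.

## Known limitations

- Only k = 2 states; no HMM or co-activation alternatives, no
  silhouette-based selection of k.
- The Louvain heuristic is only verified optimal on small graphs; on large
  graphs modularity is a lower bound, as with any heuristic.
- The Var definition is one defensible reading of "state cloud extent";
  comparisons across software should verify conventions.
- Mediation is single-mediator OLS with percentile bootstrap; no latent
  variables, robust SEs, multiple mediators, or moderated mediation.
- The generator's i.i.d.-within-state frames make windows slightly more
  informative than equally long real-data windows; recovery rates are
  therefore optimistic relative to matched real acquisitions.
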