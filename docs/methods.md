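# Methods

This note documents the models and procedures implemented in `eventbold`,
the design choices made where more than one reasonable option existed, and
what the synthetic generator does and does not emulate.

## Consensus event boundaries

Observers watching a continuous stimulus press a key at each perceived
event transition. Boundaries are derived from the pooled presses in three
deterministic steps:

1. **Greedy 1-D clustering.** Presses are pooled and sorted; a press joins
   the current cluster if it lies within `window_s` (default 5 s) of the
   running cluster mean, otherwise it opens a new cluster.
2. **Group-meaned boundary time.** The provisional cluster mean is refined
   by a flat-kernel mean shift (the time is recomputed as the mean of all
   pooled presses within `window_s` of it, iterated to convergence), and
   the final time is the mean of one estimate per agreeing observer —
   each observer's nearest press within the window. The two refinements
   matter: a bare greedy pass can sweep in a stray press from up to
   ~2·window away from the true transition, and because that press stays in
   the member list it biases the raw cluster mean. On synthetic logs
   (16 observers, 1 s jitter, 10% misses, 0.005/s false alarms) the raw
   greedy mean misses the 1 s recovery tolerance in roughly one seed in
   eight; with the refinement all of 300 test seeds recover every boundary
   within 1 s (worst error 0.95 s). The per-observer estimate also matches
   the semantics of a "group-meaned" time: an average over observers'
   boundary reports, not over raw keypresses.
3. **Filtering.** Agreement is the fraction of observers with at least one
   press within `window_s` of the boundary time; boundaries with agreement
   below `min_agreement` (default 0.5) are dropped, and of any two
   boundaries closer than `min_separation_s` (default 6 s) the
   lower-agreement one is dropped (ties drop the later one).

**Within-event control timepoints** are placed on an even grid with spacing
`duration / n_points` starting at half a spacing (when `n_points` equals
the boundary count, as in the standard analysis, this spacing is the
average elapsed time between events). Candidates closer than
`min_distance_s` (default 6 s) to a boundary are projected to the nearest
admissible time inside their event; candidates whose event has no
admissible interior are respread evenly across the admissible gaps. The
function returns exactly `n_points` times or raises naming the violated
constraint. The admissible set is inset by 1 µs so the strict "more than
6 s from any boundary" invariant survives floating-point projection onto an
interval endpoint.

**Segmentation agreement** between observer groups: each log becomes a
binary vector over 1 s bins (a bin is 1 if it contains a press), smoothed
with a 2 s Gaussian; agreement is the mean pairwise Pearson r within or
between groups. Binning and smoothing are configurable; the defaults are a
conventional choice for ~40 s events and 1–2 s motor jitter. Group
comparisons use the Fisher r-to-z statistic with the group sizes as n (the
between-group correlation uses the smaller group's n). When the two groups
are literally the same sample, a log is never paired with its own
duplicate, so identical groups give r_between = r_within exactly.

## Visual nuisance regressor

Low-level visual change co-occurs with many event boundaries, so the GLM
controls for it with a continuous regressor: the proportion of edge pixels
per frame, resampled to the TR grid. Edges are pixels whose Sobel gradient
magnitude (responses scaled by 1/8, reflect padding, so a clean unit step
reads 0.5) exceeds `grad_threshold` (default 0.2 on unit-scaled
intensities — about half the response of a full-contrast edge, insensitive
to mild interpolation ringing). Frames are assigned to the half-open TR
interval containing their temporal midpoint; a trailing empty interval
carries the previous value forward. The module is fully deterministic.
Exact numeric agreement with any particular video decoder or detector
configuration is not claimed; what matters downstream is that the regressor
carries the stimulus's visual-change envelope, and the null-calibration
test shows the GLM absorbs edge-driven signal completely.

## The GLM

Each subject × ROI percent-signal series is fit by ordinary least squares
on: HRF-convolved boundary impulses, HRF-convolved within-event impulses,
the edge regressor (unconvolved by default; a flag enables convolution),
six motion parameters plus their first differences (leading element 0), a
mean-centered linear drift, and an intercept. Events are binned at
floor(t/TR) with 0-based indexing. The HRF is the double-gamma kernel
(gamma densities with shape 6 and 16, ratio 6, peak-normalized; sampled to
32 s), a standard shape whose fitted peak lies at ~5 s. No prewhitening is
applied: with AR(1) noise OLS point estimates stay unbiased, and all
inference in this package happens *across* subjects, where each subject
contributes one independent beta — the null-calibration test verifies the
resulting one-sample t is exact. Residual SD uses n − rank degrees of
freedom. Rank-deficient designs raise an error naming the collinear
columns (diagnosed from the QR factor's diagonal).

The **adjusted beta** β_boundary − β_within isolates boundary-specific
activity from overall movie-driven activity. The **FIR model** replaces
the HRF regressors with one indicator per TR lag (default −2..+8 TRs,
≈ −5..+20 s, covering the full response) and reports the lag betas; on
noise-free non-overlapping events these reproduce the HRF samples exactly,
and with disjoint lag windows each beta equals the event-locked mean minus
the uncovered-timepoint baseline.

**Quality control** excludes a subject whose mean framewise displacement
exceeds 0.5 mm, whose maximal FD exceeds 3 mm, or whose tSNR falls more
than 2 SD below the full-cohort mean (cutoff computed before any
exclusion; all inequalities strict, so a subject at exactly the limit is
kept).

## Cohort statistics

All tests are two-sided and parametric. Age tertiles sort by age with ties
broken by subject id and split into contiguous blocks as equal as possible,
remainders to the younger groups (546 → 182/182/182; 7 → 3/2/2). One-way
ANOVA reports F, p, η² = SS_between/SS_total, and Tukey HSD adjusted
pairwise contrasts at α = 0.05. Brain-behavior prediction is unstandardized
OLS with per-coefficient t-tests; the default predictor set is all ROI
adjusted betas, head motion, the neuropsychological scores, the companion
story-recall score, and age. Sex checks use the pooled-variance two-sample
t. Voxelwise maps are thresholded with Benjamini–Hochberg step-up FDR at
q = 0.05. Standard machinery is delegated to scipy and statsmodels; this
package fixes the contracts and validates them against hand-worked and
closed-form oracles in the test suite.

The Fisher z comparison of two correlations uses the independent-samples
formula; applied to the package's headline use cases it reproduces the
reference values exactly (e.g., z = −4.95 for r = −0.345 vs −0.059 at
n = 546, and z = 0.19/0.36/0.17 for the behavioral agreement contrasts at
n = 14). A dependent-correlation correction (the two correlations share
one cohort) is deliberately not applied, since the independent formula is
what the reference values imply; this is documented rather than asserted
as anyone's intent.

## Synthetic data: what it emulates

The generator produces every input the pipeline needs, with known ground
truth, under one run seed split into fixed labeled substreams (so changing
one generator never perturbs another's draws).

* **Observers** (default 16): each true boundary is reported with
  probability 1 − miss_p (default 0.15), jittered by N(0, 1 s) and clipped
  to the stimulus; false alarms are Poisson at 0.005/s. The defaults give
  ~86% hit rates, matching behavioral segmentation samples of this kind;
  miss and false-alarm rates are configuration values, not claims about
  any particular dataset.
* **Stimulus**: 8 minutes at 6 Hz, 32×32 frames rendered from named
  patterns (uniform, vertical step, checkerboard) whose content changes at
  each true boundary, so edge density carries a genuine boundary-locked
  visual signal.
* **Cohort** (default 546 subjects): ages uniform on 18–88 (the reported
  range, with near-uniform coverage; the exact source distribution is not
  public). Motion and tSNR summaries emulate an already quality-controlled
  sample — the analysis n is meant to be the post-QC n, so the default FD
  and tSNR distributions produce essentially no exclusions; the QC logic
  itself is exercised on constructed fixtures with known violators.
* **ROI amplitudes**: true boundary beta = base + slope·(age − midpoint) +
  N(0, σ_amp). For the posterior-hippocampus-like effect ROI the defaults
  are base 0.167 (within-event 0.05, so the adjusted beta is ~0.117 at the
  age midpoint), slope −0.00138 %sig/yr — the values implied by published
  group means for this contrast — and σ_amp *calibrated* to a target
  age-beta correlation of −0.345 by the attenuation identity
  ρ = slope·σ_age / √(slope²σ_age² + σ_amp²). Because the pipeline
  correlates age with *measured* betas, the GLM's own contrast sampling
  variance (computed in closed form as σ²·c X⁺ V X⁺ᵀ cᵀ with V the AR(1)
  correlation) is subtracted from the noise budget first; this keeps the
  target exact through the full pipeline rather than only for the latent
  amplitudes. ROI noise is stationary AR(1) with marginal SD 0.12 %sig and
  lag-1 coefficient 0.3 — appropriate for ROI-averaged series, and small
  enough that between-subject amplitude variance dominates measurement
  error, as the reference effect sizes require.
* **Memory scores**: delayed story recall loads on immediate recall
  (weight 0.883), on the pHPC amplitude deviation (coupling 3.08 points
  per unit beta), and on age (−0.0194/yr) with residual SD 2.5; immediate
  recall and the other neuropsychological scores decline linearly with age
  with Gaussian noise. These constants reproduce the expected marginal
  structure (age-memory r ≈ −0.3, beta-memory r ≈ 0.15–0.21) at n = 546.

What the generator does **not** emulate: voxel-level spatial covariance,
multi-echo acquisition, motion image artifacts (motion exists only as
regressor values and FD summaries), integer-valued test scores (rounding is
a flag, off by default), realistic video content, or non-uniform age
sampling. Passing tests therefore demonstrate correctness of the analysis
machinery and recoverability of effects under the stated generative
assumptions — not robustness to preprocessing failures or to real-video
edge statistics.

## Problem sizes and runtime choices

The validation suite uses the study-scale configuration where the claim
depends on it — 546 subjects × 193 TRs × 12 boundaries, 100 seeded
replicates for the recovery checks, 400 boundary-free cohorts of 50 for
type-I calibration — and small constructed instances everywhere the
property is exact (oracle equivalence, degenerate inputs, invariants). A
single full pipeline run takes about 1.5 s on one CPU; the complete test
suite runs in a few minutes.

One statistical note on the calibration check: "rejection rate within the
binomial 95% interval" is itself a 95% test, so any fixed-seed
instantiation fails with probability 0.05 under a perfectly calibrated
statistic, independent of the number of cohorts. The suite pins one seed
and uses the exact binomial acceptance region (12–29 rejections out of
400 at α = 0.05) rather than the normal approximation.

## Configuration and provenance

Runs are driven by a YAML-loadable `RunConfig` validated by explicit
dataclass checks (unknown keys, ranges, path existence in files mode).
Every report embeds the SHA-256 hash of the canonical config JSON, the
seed, and the package version; reruns with the same config and seed are
byte-identical. File interfaces are plain text: keypress TSV
(`observer_id`, `press_time_s`), boundary and within-event TSVs, per-frame
edge CSV (`frame_index`, `edge_proportion`), per-TR regressor TSV, design
matrix TSV, cohort and betas CSV, JSON reports.

## Known limitations

* The edge detector and HRF are fixed, reasonable choices; analyses whose
  conclusions hinge on detector thresholds or HRF shape should sweep the
  exposed parameters.
* OLS standard errors *within* a subject are not AR-corrected; only the
  across-subject inference path is validated as exact.
* The brain-behavior regression at the published effect size recovers the
  coefficient's sign reliably but reaches single-cohort significance only
  sporadically — as expected for a t ≈ 2 effect — so tests assert recovery
  properties, not significance, for that coefficient.
* Files mode fits all subjects with one shared design apart from optional
  per-subject motion files; per-subject event timing (e.g., individualized
  boundary reports) is out of scope.
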