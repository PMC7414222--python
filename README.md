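# eventbold

Boundary-evoked BOLD activity analysis for naturalistic event segmentation.

When people watch a continuous film, they spontaneously parse it into
discrete events; moments of transition — **event boundaries** — evoke
transient responses in the hippocampus and the Posterior Medial (PM)
cortical network, and the amplitude of these responses changes across the
adult lifespan and tracks episodic memory ability. `eventbold` is a tested,
reusable implementation of the full analysis path from raw observer
keypresses to cohort-level statistics, aimed at researchers working with
movie-watching fMRI (e.g., lifespan datasets such as CamCAN) and at anyone
who wants to validate or extend this class of analysis on synthetic data
with known ground truth.

## What it computes

1. **Consensus boundaries** — multiple observers' keypress logs are pooled
   and clustered; a timepoint becomes a boundary when at least half the
   observers agree within 5 s of the group-meaned time, with boundaries no
   closer than 6 s. Matched **within-event** control timepoints are placed
   evenly through the stimulus, more than 6 s from any boundary.
2. **Per-subject GLM** — each ROI's percent-signal-change series *y* is fit
   by OLS:

   *y* = β_b·(HRF ∗ boundary impulses) + β_w·(HRF ∗ within impulses)
   + β_e·edge + Σ motion (6 params + derivatives) + drift + intercept + ε,

   where *edge* is the per-TR proportion of edge pixels in the stimulus
   frames (a low-level visual nuisance regressor) and the HRF is a
   double-gamma kernel (peak 6 s, undershoot 16 s). The quantity of interest
   is the **adjusted beta** β_b − β_w: boundary-specific activity over and
   above within-event activity. An FIR variant estimates the boundary-locked
   timecourse lag by lag without assuming an HRF shape.
3. **Cohort statistics** — one-sample t-tests of adjusted betas, Pearson
   correlations with age, equal-size age tertiles compared by one-way ANOVA
   with Tukey HSD and η², Fisher r-to-z contrasts between correlations
   (z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))), pooled-variance sex
   checks, OLS brain-behavior regression, and Benjamini–Hochberg FDR for
   voxelwise grids.
4. **Synthetic forward model** — observers (jitter, misses, false alarms),
   stimulus frames with controlled edge density, an adult-lifespan cohort
   whose boundary-response amplitudes decline linearly with age, and ROI
   BOLD as design × true betas + AR(1) noise. Every downstream stage is
   therefore testable against known ground truth.

## Worked example

```python
from eventbold import fisher_z_compare
from eventbold.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))   # 546 subjects, 193 TRs at 2.47 s
```

With the default configuration (16 observers segmenting an 8-minute
stimulus with 12 true boundaries; a posterior-hippocampus-like ROI whose
boundary response declines with age targeting r = −0.345; anterior-
hippocampal and visual-cortex control ROIs), the report prints:

```
consensus boundaries : 12 (first three at 22.0, 65.4, 101.2 s)
observer hit rate    : 89.1%
pHPC boundary activity: t(545) = 35.59
pHPC age correlation  : r = -0.366 (p = 9.60e-19)
aHPC age correlation  : r = -0.011 (p = 0.80)
tertile ANOVA (pHPC)  : F(2, 543) = 35.52, eta^2 = 0.116
pHPC vs aHPC age corr : z = -6.14 (p = 8.2e-10)
pHPC -> delayed recall: b = 2.23 (p = 0.126)
```

Reading this: the 12 generative boundaries are recovered exactly; the
effect ROI shows strong boundary-evoked activity whose amplitude declines
with age (single-seed r fluctuates around the −0.345 target with sampling
SD ≈ 0.038 at n = 546); the control ROI shows no age trend, and the Fisher
z confirms the two correlations differ; the regression coefficient of
delayed story recall on pHPC activity is positive (its generative value is
3.08 points per unit beta; at this effect size single cohorts recover the
sign but not always significance).

## Command line

```sh
eventbold run --config cfg.yaml --seed 7 --out results/   # full pipeline
eventbold simulate --seed 3 --out sim/                    # synthetic inputs
eventbold boundaries --in presses.tsv --out boundaries.tsv \
    --within-out within.tsv
eventbold design --boundaries boundaries.tsv --within within.tsv \
    --edge edge_per_tr.tsv --n-tr 193 --out design.tsv
eventbold fit --design design.tsv --series roi_series.tsv --out betas.csv
eventbold stats --betas betas.csv --cohort cohort.csv --out stats.json
```

Runs are bit-reproducible given (config, seed); every report embeds the
config hash and seed.

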