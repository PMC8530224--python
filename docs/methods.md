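# Methods

This note documents the statistical models, numerical choices and synthetic
data underlying `scanagree`, and what the test suite does and does not
establish about real scan–rescan data.

## Study design assumed

The analysis targets a balanced repeated-measures design: `n` subjects, each
scanned `r = 2` times on each of `k` scanners within a short interval (so
true anatomy is constant), with eleven brain structure volumes extracted per
scan by an automated segmentation pipeline. Intra-scanner agreement compares
the two repetitions within a scanner; inter-scanner agreement compares the
per-scanner means of the two repetitions, pairwise or jointly across all
scanners.

## Simulated volume tables

`simulate_volume_table` draws

    v[i, s, t] = b[s] · (μ + u_i) · (1 + ε[i, s, t])

per structure, with subject effect `u_i ~ N(0, σ_A²)` shared across all
scans of a subject and residual `ε ~ N(0, (c/100)²)` independent per
measurement. The residual is **multiplicative** (a CV, not an SD): observed
scan–rescan noise scales with structure volume across three orders of
magnitude (≈3 mL hippocampus to ≈1.1 L whole brain), so a single scale-free
noise parameter covers all structures. Non-positive draws are resampled, not
clipped, to avoid a point mass at zero (relevant only for high-CV structures
such as lateral ventricles, population CV ≈ 34%).

Defaults encode the published study conditions:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 10 | study size |
| scanners | achieva, ingenia, ge | the three MRI systems |
| n_repetitions | 2 | scan–rescan |
| structure means/SDs | published all-scanner volume table | e.g. whole brain 1138.20 ± 126.33 mL |
| scanner bias `b[s]` | per-scanner published mean / pooled mean | e.g. GE white matter ≈ +5.4% |
| residual CV `c` | 1.316% | `E[pair CV] = √(2/π)·c`; calibrated to the ≈1.05% published intra-scanner grand mean |

For a pair of measurements the CV is `|v₁ − v₂| / (√2 · mean) · 100`, whose
expectation under the model is `√(2/π)·c` and whose mean square converges to
`c²` (a tested invariant). No cross-structure correlation is modelled (one
independent subject effect per structure): the source study reports no
covariance information, so joint statements across structures (e.g. a
subject being an outlier everywhere at once) are outside what the simulator
can support.

## Phantom image pairs

`generate_phantom_pair` builds 64³ images at 2 mm spacing (defaults) from
nested ellipsoid shells — CSF (dark), GM, WM (bright), plus two small
hippocampus-like blobs inside the WM shell — with additive Gaussian noise
(SD 2 on a 0–100 intensity scale). The second image is the analytic template
evaluated through the *inverse* of a configurable ground-truth affine, so no
interpolation error enters the ground truth; its GM–WM intensity gap can be
rescaled (`contrast_scale`) and its noise is fresh. Label maps come from the
same analytic geometry.

What this phantom exercises: affine registration and its failure modes, NMI
similarity, CNR, label resampling and Dice, with an exact oracle transform.
What it does not emulate: cortical folding, partial-volume mixtures, bias
fields, MRI noise statistics (Rician, coil profiles) — so passing phantom
tests demonstrates correctness of the measurement machinery, not
segmentation robustness on real anatomy. Voxelization matters for small
structures: the blobs span only ~90 voxels at 2 mm, and their voxel-counted
volume can alias by >10% under a rigid transform, whereas the shells stay
within 2%.

## Registration

`register_affine` is a three-level (shrink 4/2/1, smoothing 2/1/0 mm)
Mattes mutual-information registration with dense sampling (deterministic),
moments-based initialization, regular-step gradient descent, and a 12-DOF
affine model. On same-sequence piecewise-smooth images the 32-bin MI surface
turned out to be almost flat across sub-percent scale changes (the optimizer
settled at scale 1.037 for a true 1.02); a short correlation-metric polish
stage, started from the MI solution, restores a sharp optimum and sub-voxel
accuracy (translation error ~0.003 mm, scale error ~0.001 on phantoms). The
polish is on by default and can be disabled (`refine_correlation=False`)
for genuinely multi-modal pairs. A registration stopping on its iteration
limit is returned flagged (`converged=False`) with the optimizer's stop
description, never silently.

The returned transform maps moving-image physical coordinates to fixed-image
physical coordinates; resampling uses its inverse, per the ITK convention.

## Affine similarity index (NMI)

Among the several NMI normalizations in use, the symmetric uncertainty
`2·I(A;B)/(H(A)+H(B)) ∈ [0, 1]` is adopted: it is the only common variant
compatible with the published operating range of the index (values 0.20–0.37
with a reliability threshold at 0.2; the entropy-ratio variant is ≥ 1 by
construction). Intensities are clamped to their 1st–99th percentiles over
the overlap region of the aligned images (robustness to tails), then binned
into 32 equal-width bins per image. Identical aligned images score exactly
1; independent noise scores ≈ (bins−1)²/(2 N ln 2 · H), ≈ 5·10⁻⁴ at 64³.
Constant images have zero entropy and raise an error.

## CNR

`CNR = |mean_GM − mean_WM| / sqrt(var_GM + var_WM)`, the standard
contrast-to-noise definition with the pooled-variance square root in the
denominator. Tissue masks taken from a label map are eroded by one voxel to
exclude partial-volume boundary voxels.

## ICC

`icc_absolute_single` implements ICC(A,1) — two-way, absolute agreement,
single measurement — from the two-way mean squares:

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with the 95% CI from the F distribution using Satterthwaite denominator
degrees of freedom (the McGraw–Wong interval, verified against an
independent reference implementation to its printed precision). The one-way
variance-component form `σ_A²/(σ_A² + σ_W²)` is returned as a diagnostic;
the two coincide when the column mean square equals the error mean square.
Classification uses the point estimate with half-open bands
[0.50, 0.75) moderate, [0.75, 0.90) good, ≥ 0.90 excellent; the band of the
CI lower bound is reported alongside as the conservative reading. Perfect
agreement (zero error and column mean squares) yields the degenerate
interval [1, 1]. Incomplete matrices are rejected — no imputation.

## Aggregation conventions

Sample SD (n−1) is used throughout, including two-value pair CVs — this is
what makes the percentual difference exactly √2 × CV and is validated by the
pooled-demographics reproduction (pooling (5, 52.2, 17.6) and
(5, 69.0, 10.5) gives exactly 60.6 ± 16.3 to one decimal). The
"all volumes" summary row is the **unweighted mean (± SD) across the eleven
per-structure means**, not the pooled subject-level mean; this convention
reproduces the published all-volumes rows (1.05 ± 0.87, 1.15, 0.95; DSC
0.93; inter-scanner 2.90 and 2.55) from the printed per-structure values.
AVD and percentual difference are pairwise-only and are omitted from the
all-scanner comparison.

## Bland–Altman and acceptability

Bias = mean difference (test − retest), LOA = bias ± 1.96 SD (sample SD).
Confidence intervals use the classical approximations SE(bias) = SD/√n and
SE(LOA) = SD·√(3/n) with a `t(n−1)` quantile. A pair is an outlier when its
difference exceeds the upper limit of the upper-LOA CI or falls below the
lower limit of the lower-LOA CI — the rule evaluated literally per point.
Note a structural property of this rule: a single aberrant pair inflates the
SD it is judged against, so isolated gross outliers in very small samples
may not be flagged; flagging requires the discrepant difference to exceed
the LOA CI built mostly from the concordant pairs (e.g. one +10 mL
difference among twenty ~0 mL differences is flagged).

Acceptability converts both LOA to a percentage of the mean structure
volume and accepts when neither exceeds the class threshold — 2.0% for
large structures, 4.66% for hippocampal volumes (annual pathological
atrophy rates in AD) — with the boundary counting as acceptable, and no
pair outside the LOA CIs.

## Scanner-effect mixed model

`fit_scanner_effect_model` fits `y = μ + β_level + u_subject + ε` on a
balanced long table by the closed-form REML solution for
single-random-intercept balanced designs: `σ_e²` is the residual mean
square of the additive two-way model, `σ_u² = (MS_subject − σ_e²)/(k r)`
(truncated at zero with a warning — the method-of-moments boundary case).
These equal iterative REML on balanced data (verified against an
independent mixed-model implementation to ~1e-5 and against the restricted
likelihood directly). Pairwise level contrasts are reported with their Wald
statistic `z = estimate / SE`, `SE = √(2 σ_e² / (n r))`. The p-value uses
the exact `t` reference distribution with the residual degrees of freedom
`nkr − n − k + 1` rather than the normal: on designs this small (n = 10),
normal-based p-values inflate the false-positive rate at α = 0.005 by
~40%, while the t reference is exact under the model (the simulated
type-I error matches nominal within Monte-Carlo error). Bonferroni
multiplies p by the number of structures analysed (11) and caps at 1;
significance is declared at raw p < 0.005 (= 0.05/11).

## Problem sizes in tests and acceptance runs

Simulation-based checks use 500 replicates at the study size (n = 10);
oracle-equivalence checks use 100 random instances; registration recovery
uses three 64³ phantom pairs (translation 2 mm, uniform scale 1.02, rigid
rotation + translation). The full suite and the acceptance script each
complete in a couple of minutes on a single core.

## Known limitations

- Balanced complete designs only; missing cells are an error, not imputed.
- CV/AVD/DSC are bounded, non-negative quantities but are modelled on the
  raw scale in the mixed model, as the study design implies.
- The Bland–Altman outlier rule inherits the small-sample insensitivity
  described above.
- The simulator's multiplicative-noise and no-cross-structure-correlation
  assumptions are back-calculated from published summary tables; real
  variance components of the source data were not published.
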