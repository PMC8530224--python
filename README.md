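# scanagree

Intra- and inter-scanner agreement analysis for automated brain MRI
volumetry.

## The problem

Automated volumetry of T1-weighted brain MRI (whole brain, gray and white
matter, cortical lobes, hippocampi, lateral ventricles) is increasingly used
in the diagnostic work-up of Alzheimer's disease. Its clinical value hinges
on measurement precision: if the same head, scanned twice on the same
scanner — or on scanners from different vendors with harmonized protocols —
yields volumes that differ by more than the annual pathological atrophy rate
(~2% for large structures, ~4.66%/yr for hippocampi in AD), scanner effects
can swamp the biology. `scanagree` implements the complete scan–rescan
agreement analysis for such studies: ten subjects, two repetitions on each
of three MRI systems, eleven brain structures.

It is written for imaging scientists and biostatisticians validating
volumetry pipelines, and ships a synthetic-data module (simulated volume
tables with a known variance structure, and ellipsoid-shell head phantoms
with known ground-truth affines) so that the whole analysis is exercisable
and testable without patient data.

## What it computes

**Image level** (`scanagree.image_metrics`)

- 12-DOF affine registration (multi-resolution, mutual-information driven,
  with a same-modality correlation polish stage);
- affine similarity index: normalized mutual information
  `NMI = 2 I(A;B) / (H(A) + H(B))` between the aligned images, in [0, 1];
  alignment is considered reliable above 0.2;
- maximum scaling factor: largest principal stretch of the affine,
  `max_i max(s_i, 1/s_i)` over the singular values `s_i` (stretching and
  shrinking are inverse operations);
- WM/GM contrast-to-noise ratio
  `CNR = |mean_GM − mean_WM| / sqrt(var_GM + var_WM)`;
- Dice similarity after nearest-neighbour label resampling,
  `DSC(X, Y) = 2|X ∩ Y| / (|X| + |Y|)`.

**Volume level** (`scanagree.agreement`)

- pair coefficient of variation `CV(%) = σ/μ × 100` (sample SD), absolute
  volume difference (mL), percentual difference (= √2 × CV, exactly);
- ICC(A,1): two-way, absolute-agreement, single-measure intraclass
  correlation with F-based 95% CIs, classified poor / moderate / good /
  excellent at 0.50 / 0.75 / 0.90;
- the study aggregation scheme: per-structure mean ± SD over subjects,
  intra-scanner (two repetitions), pairwise inter-scanner and all-scanner
  comparisons on the per-scanner repetition means, and an unweighted
  "all volumes" summary row across structures.

**Patient level** (`scanagree.reliability`)

- Bland–Altman bias and limits of agreement (bias ± 1.96 SD) with
  confidence intervals and an outlier rule, plus clinical acceptability
  against the 2% / 4.66% maximum allowed difference;
- a random-intercept mixed model `y = μ + β_scanner + u_subject + ε`
  (closed-form REML on balanced designs) with pairwise Wald contrasts and
  Bonferroni correction across the 11 structures (α = 0.005).

## Worked example

```python
from scanagree import SimulationConfig, simulate_volume_table, summarize_agreement

records = simulate_volume_table(SimulationConfig(seed=1))   # 660 measurements
intra = summarize_agreement(records, mode="intra")
cols = ["structure", "comparison", "cv_mean", "cv_sd", "avd_mean", "icc", "icc_class"]
keep = intra.data["structure"].isin(["whole_brain", "hippocampus_left", "all_volumes"])
print(intra.data[keep][cols].round(3).to_string(index=False))
```

prints

```
       structure comparison  cv_mean  cv_sd  avd_mean   icc icc_class
     whole_brain    achieva    0.474  0.356     7.910 0.993 excellent
hippocampus_left    achieva    0.962  0.450     0.046 0.994 excellent
     whole_brain    ingenia    0.947  0.854    15.013 0.971 excellent
hippocampus_left    ingenia    1.289  0.875     0.061 0.989 excellent
     whole_brain         ge    0.780  0.756    12.308 0.980 excellent
hippocampus_left         ge    1.535  0.818     0.074 0.987 excellent
     all_volumes    achieva    1.083  0.368     3.798 0.980 excellent
     all_volumes    ingenia    1.021  0.243     4.451 0.983 excellent
     all_volumes         ge    1.071  0.285     4.200 0.975 excellent
```

Each row is one structure on one scanner: the mean ± SD over the ten
subjects of the scan–rescan CV and absolute difference, and the ICC of the
subjects × repetitions matrix. The `all_volumes` rows are unweighted means
across the eleven per-structure means — the simulated intra-scanner grand
mean CV of ~1% with excellent ICCs reproduces the regime the default
simulation parameters encode.

The same pipeline runs from the shell:

```sh
scanagree simulate --seed 1 --out volumes.csv --phantom-dir phantom/
scanagree agreement --volumes volumes.csv --mode intra --out intra.csv
scanagree report --volumes volumes.csv --out report/
scanagree image-metrics --fixed phantom/image_b.nii.gz --moving phantom/image_a.nii.gz \
    --labels-fixed phantom/labels_b.nii.gz --labels-moving phantom/labels_a.nii.gz \
    --label-names phantom/label_names.json --out metrics.json
```

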