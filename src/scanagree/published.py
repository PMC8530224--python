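"""Reference agreement values from a published three-scanner volumetry study.

A scan-rescan reproducibility study of automated brain volumetry scanned ten
participants (five healthy controls, five on the AD continuum) twice on each
of three MRI systems — a Philips Achieva dStream 1.5T, a Philips Ingenia 3T
and a GE Discovery MR750w 3T — and reported per-structure agreement metrics
for eleven brain structures.  The per-structure values below calibrate the
synthetic study generator and validate the aggregation conventions (the
"All volumes" summary rows are unweighted means across structures).

Volumes are in mL, CVs and percentual differences in %, DSC unitless.
"""

from __future__ import annotations

SCANNERS = ("achieva", "ingenia", "ge")

#: canonical structure order used throughout
STRUCTURES = (
    "whole_brain",
    "gray_matter",
    "cortical_gray_matter",
    "white_matter",
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "hippocampus_total",
    "hippocampus_left",
    "hippocampus_right",
    "lateral_ventricles",
)

#: acceptability class per structure: hippocampal volumes tolerate a larger
#: scan-rescan difference (4.66%/yr pathological atrophy) than large
#: structures (~2%/yr).
STRUCTURE_CLASS = {
    name: ("hippocampus" if name.startswith("hippocampus") else "large")
    for name in STRUCTURES
}

#: pooled (all-scanner) actual volumes, mean +/- between-subject SD, in mL
ACTUAL_VOLUMES_ML = {
    "whole_brain": (1138.20, 126.33),
    "gray_matter": (670.47, 81.77),
    "cortical_gray_matter": (639.37, 79.99),
    "white_matter": (467.73, 53.43),
    "frontal_cortex": (175.93, 23.99),
    "parietal_cortex": (109.54, 15.14),
    "temporal_cortex": (116.54, 13.97),
    "hippocampus_total": (6.91, 0.94),
    "hippocampus_left": (3.40, 0.47),
    "hippocampus_right": (3.51, 0.49),
    "lateral_ventricles": (34.89, 11.96),
}

#: per-scanner mean actual volumes (mL); ratios to the pooled mean define the
#: default multiplicative scanner bias of the simulator.
SCANNER_MEAN_VOLUMES_ML = {
    "achieva": {
        "whole_brain": 1139.77,
        "gray_matter": 683.08,
        "cortical_gray_matter": 650.81,
        "white_matter": 456.69,
        "frontal_cortex": 180.02,
        "parietal_cortex": 111.81,
        "temporal_cortex": 118.04,
        "hippocampus_total": 6.89,
        "hippocampus_left": 3.35,
        "hippocampus_right": 3.54,
        "lateral_ventricles": 34.67,
    },
    "ingenia": {
        "whole_brain": 1132.64,
        "gray_matter": 679.19,
        "cortical_gray_matter": 646.72,
        "white_matter": 453.45,
        "frontal_cortex": 179.09,
        "parietal_cortex": 111.75,
        "temporal_cortex": 116.31,
        "hippocampus_total": 6.92,
        "hippocampus_left": 3.38,
        "hippocampus_right": 3.55,
        "lateral_ventricles": 35.44,
    },
    "ge": {
        "whole_brain": 1142.20,
        "gray_matter": 649.16,
        "cortical_gray_matter": 620.57,
        "white_matter": 493.04,
        "frontal_cortex": 168.67,
        "parietal_cortex": 105.07,
        "temporal_cortex": 115.25,
        "hippocampus_total": 6.92,
        "hippocampus_left": 3.46,
        "hippocampus_right": 3.45,
        "lateral_ventricles": 34.55,
    },
}

#: per-structure intra-scanner scan-rescan CV means (%), by scanner
INTRA_CV_MEAN = {
    "achieva": {
        "whole_brain": 0.18,
        "gray_matter": 0.16,
        "cortical_gray_matter": 0.29,
        "white_matter": 0.46,
        "frontal_cortex": 0.60,
        "parietal_cortex": 1.58,
        "temporal_cortex": 1.94,
        "hippocampus_total": 1.44,
        "hippocampus_left": 2.90,
        "hippocampus_right": 1.35,
        "lateral_ventricles": 0.66,
    },
    "ingenia": {
        "whole_brain": 0.21,
        "gray_matter": 0.52,
        "cortical_gray_matter": 0.54,
        "white_matter": 1.06,
        "frontal_cortex": 0.63,
        "parietal_cortex": 1.52,
        "temporal_cortex": 1.56,
        "hippocampus_total": 1.63,
        "hippocampus_left": 3.14,
        "hippocampus_right": 1.11,
        "lateral_ventricles": 0.75,
    },
    "ge": {
        "whole_brain": 0.29,
        "gray_matter": 0.43,
        "cortical_gray_matter": 0.38,
        "white_matter": 0.74,
        "frontal_cortex": 0.99,
        "parietal_cortex": 1.78,
        "temporal_cortex": 1.11,
        "hippocampus_total": 0.95,
        "hippocampus_left": 1.46,
        "hippocampus_right": 1.16,
        "lateral_ventricles": 1.13,
    },
}

#: per-structure intra-scanner DSC means, by scanner
INTRA_DSC_MEAN = {
    "achieva": {
        "whole_brain": 0.92,
        "gray_matter": 0.93,
        "cortical_gray_matter": 0.93,
        "white_matter": 0.94,
        "frontal_cortex": 0.90,
        "parietal_cortex": 0.87,
        "temporal_cortex": 0.89,
        "hippocampus_total": 0.90,
        "hippocampus_left": 0.90,
        "hippocampus_right": 0.91,
        "lateral_ventricles": 0.96,
    },
    "ingenia": {
        "whole_brain": 0.98,
        "gray_matter": 0.92,
        "cortical_gray_matter": 0.92,
        "white_matter": 0.94,
        "frontal_cortex": 0.90,
        "parietal_cortex": 0.87,
        "temporal_cortex": 0.90,
        "hippocampus_total": 0.91,
        "hippocampus_left": 0.90,
        "hippocampus_right": 0.91,
        "lateral_ventricles": 0.96,
    },
    "ge": {
        "whole_brain": 0.98,
        "gray_matter": 0.93,
        "cortical_gray_matter": 0.93,
        "white_matter": 0.94,
        "frontal_cortex": 0.89,
        "parietal_cortex": 0.87,
        "temporal_cortex": 0.90,
        "hippocampus_total": 0.93,
        "hippocampus_left": 0.92,
        "hippocampus_right": 0.93,
        "lateral_ventricles": 0.97,
    },
}

#: per-structure inter-scanner CV means (%), per scanner comparison
INTER_CV_MEAN = {
    "all_scanners": {
        "whole_brain": 0.53,
        "gray_matter": 2.88,
        "cortical_gray_matter": 2.69,
        "white_matter": 4.75,
        "frontal_cortex": 3.71,
        "parietal_cortex": 3.85,
        "temporal_cortex": 1.77,
        "hippocampus_total": 1.64,
        "hippocampus_left": 2.64,
        "hippocampus_right": 2.12,
        "lateral_ventricles": 1.45,
    },
    "ingenia-achieva": {
        "whole_brain": 0.49,
        "gray_matter": 0.44,
        "cortical_gray_matter": 0.57,
        "white_matter": 0.76,
        "frontal_cortex": 0.49,
        "parietal_cortex": 0.74,
        "temporal_cortex": 1.42,
        "hippocampus_total": 1.14,
        "hippocampus_left": 2.08,
        "hippocampus_right": 1.16,
        "lateral_ventricles": 1.54,
    },
    "achieva-ge": {
        "whole_brain": 0.36,
        "gray_matter": 3.73,
        "cortical_gray_matter": 3.49,
        "white_matter": 5.46,
        "frontal_cortex": 4.72,
        "parietal_cortex": 4.70,
        "temporal_cortex": 2.29,
        "hippocampus_total": 1.52,
        "hippocampus_left": 2.68,
        "hippocampus_right": 2.27,
        "lateral_ventricles": 0.70,
    },
    "ingenia-ge": {
        "whole_brain": 0.58,
        "gray_matter": 3.30,
        "cortical_gray_matter": 3.02,
        "white_matter": 5.93,
        "frontal_cortex": 4.39,
        "parietal_cortex": 4.65,
        "temporal_cortex": 1.22,
        "hippocampus_total": 1.80,
        "hippocampus_left": 2.43,
        "hippocampus_right": 2.16,
        "lateral_ventricles": 1.56,
    },
}

#: demographic subgroups (n, age mean, age SD) used by the pooled-stats check
DEMOGRAPHIC_GROUPS = {
    "healthy_control": (5, 52.2, 17.6),
    "ad_continuum": (5, 69.0, 10.5),
}
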