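"""Patient-level reliability: Bland-Altman agreement and scanner-effect models.

Bland-Altman analysis plots the test-retest difference against the pair mean
and summarises it as the mean bias with limits of agreement (LOA,
bias +/- 1.96 SD of the differences).  Confidence intervals use the
classical approximations SE(bias) = SD/sqrt(n) and SE(LOA) = SD sqrt(3/n)
with a t quantile.  A measurement pair is flagged as an outlier when its
difference exceeds the outer bound of the LOA confidence intervals, and a
structure is clinically acceptable when its LOA, as a percentage of the mean
volume, stay within the annual pathological atrophy change: about 2% for
larger structures and 4.66% for hippocampal volumes.

The scanner-effect model is a linear mixed model with a random subject
intercept and the scanner (or scanner-pair) level as a fixed effect, fitted
by the closed-form REML solution available for balanced single-random-
intercept designs (identical to the ANOVA method-of-moments estimates).
Pairwise contrasts are reported with their Wald z statistic; p-values use
the exact t reference distribution of the balanced design, with Bonferroni
correction across the 11 analysed structures and significance declared at
p < 0.005.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BAResult",
    "AcceptabilityRule",
    "AcceptabilityReport",
    "MixedModelResult",
    "bland_altman",
    "acceptability",
    "fit_scanner_effect_model",
    "MAX_ALLOWED_PERCENT",
    "N_STRUCTURES_BONFERRONI",
]

#: clinically motivated maximum allowed scan-rescan difference (% of volume)
MAX_ALLOWED_PERCENT = {"large": 2.0, "hippocampus": 4.66}

#: Bonferroni multiplier: the number of analysed brain structures
N_STRUCTURES_BONFERRONI = 11


@dataclass
class BAResult:
    """Bland-Altman summary of paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple
    ci_loa_low: tuple
    ci_loa_high: tuple
    n_pairs: int
    outliers: list
    differences: np.ndarray = field(repr=False, default=None)
    means: np.ndarray = field(repr=False, default=None)
    subject_ids: list = field(repr=False, default=None)


def bland_altman(pairs, subject_ids=None, loa_factor: float = 1.96) -> BAResult:
    """Bland-Altman analysis of (scan1, scan2) pairs.

    Differences are scan1 - scan2 (test minus retest).  Outliers are pairs
    whose difference lies above the upper limit of the upper-LOA 95% CI or
    below the lower limit of the lower-LOA 95% CI.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of measurement pairs")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    if subject_ids is None:
        subject_ids = list(range(1, n + 1))

    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low = bias - loa_factor * sd
    loa_high = bias + loa_factor * sd

    t = stats.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    ci_bias = (bias - t * se_bias, bias + t * se_bias)
    ci_loa_low = (loa_low - t * se_loa, loa_low + t * se_loa)
    ci_loa_high = (loa_high - t * se_loa, loa_high + t * se_loa)

    outliers = [
        sid
        for sid, d in zip(subject_ids, diffs)
        if d > ci_loa_high[1] or d < ci_loa_low[0]
    ]
    return BAResult(
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_bias=tuple(map(float, ci_bias)),
        ci_loa_low=tuple(map(float, ci_loa_low)),
        ci_loa_high=tuple(map(float, ci_loa_high)),
        n_pairs=n,
        outliers=outliers,
        differences=diffs,
        means=means,
        subject_ids=list(subject_ids),
    )


@dataclass
class AcceptabilityRule:
    """Clinical acceptability threshold for one structure class."""

    structure_class: str = "large"
    max_allowed_percent: float = None

    def __post_init__(self) -> None:
        if self.max_allowed_percent is None:
            self.max_allowed_percent = MAX_ALLOWED_PERCENT[self.structure_class]
        if self.max_allowed_percent <= 0:
            raise ValueError("max_allowed_percent must be > 0")


@dataclass
class AcceptabilityReport:
    accepted: bool
    loa_low_percent: float
    loa_high_percent: float
    max_allowed_percent: float
    n_outliers: int
    reasons: list


def acceptability(result: BAResult, mean_volume: float, rule: AcceptabilityRule) -> AcceptabilityReport:
    """Whether the LOA stay within the clinically allowed difference.

    Both LOA, expressed as a percentage of the mean volume, must not exceed
    the threshold (boundary counts as acceptable), and no pair may fall
    outside the LOA confidence intervals.
    """
    if mean_volume <= 0:
        raise ValueError("mean volume must be positive")
    low_pct = abs(result.loa_low) / mean_volume * 100.0
    high_pct = abs(result.loa_high) / mean_volume * 100.0
    reasons = []
    if max(low_pct, high_pct) > rule.max_allowed_percent:
        reasons.append(
            f"LOA {max(low_pct, high_pct):.2f}% exceeds allowed {rule.max_allowed_percent}%"
        )
    if result.outliers:
        reasons.append(f"{len(result.outliers)} pair(s) outside the LOA confidence intervals")
    return AcceptabilityReport(
        accepted=not reasons,
        loa_low_percent=float(low_pct),
        loa_high_percent=float(high_pct),
        max_allowed_percent=rule.max_allowed_percent,
        n_outliers=len(result.outliers),
        reasons=reasons,
    )


@dataclass
class MixedModelResult:
    """Random-intercept model fit with pairwise fixed-effect contrasts."""

    fixed_effects: pd.DataFrame  # contrast, estimate, se, z, p, p_bonferroni, significant
    variance_components: dict  # subject_var, residual_var
    level_means: dict
    alpha: float = 0.005
    residual_df: float = 0.0
    method: str = "reml-closed-form"


def fit_scanner_effect_model(
    data: pd.DataFrame,
    value_col: str = "value",
    level_col: str = "level",
    subject_col: str = "subject_id",
    alpha: float = 0.005,
    n_comparisons: int = N_STRUCTURES_BONFERRONI,
) -> MixedModelResult:
    """Fit y = mu + beta_level + u_subject + eps on a balanced long table.

    The design must be balanced: every subject appears at every level with
    the same number of replicates r >= 1.  For such designs the REML
    variance components have the closed ANOVA form

        sigma_e^2 = residual MS of the additive two-way model
        sigma_u^2 = (MS_subject - sigma_e^2) / (k r)

    (truncated at zero with a warning when the subject MS falls below the
    residual MS).  Each pairwise level contrast is reported with its Wald
    statistic z = estimate/SE; p-values come from the exact t distribution
    with the residual degrees of freedom, Bonferroni-multiplied by the
    number of structures analysed.
    """
    df = data[[subject_col, level_col, value_col]].dropna()
    counts = df.groupby([subject_col, level_col]).size()
    subjects = df[subject_col].unique()
    levels = list(df[level_col].unique())
    n, k = len(subjects), len(levels)
    if n < 3 or k < 2:
        raise ValueError("need >=3 subjects and >=2 levels")
    if counts.nunique() != 1 or len(counts) != n * k:
        raise ValueError("unbalanced design: every subject needs the same replicates at every level")
    r = int(counts.iloc[0])

    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    subj_means = df.groupby(subject_col)[value_col].mean()
    lvl_means = df.groupby(level_col)[value_col].mean()

    ss_total = float(np.sum((y - grand) ** 2))
    ss_subj = k * r * float(np.sum((subj_means.to_numpy() - grand) ** 2))
    ss_lvl = n * r * float(np.sum((lvl_means.to_numpy() - grand) ** 2))
    df_resid = n * k * r - n - k + 1
    sigma_e2 = max((ss_total - ss_subj - ss_lvl) / df_resid, 0.0)
    ms_subj = ss_subj / (n - 1)
    sigma_u2 = (ms_subj - sigma_e2) / (k * r)
    if sigma_u2 < 0:
        warnings.warn(
            "subject variance component negative; truncated to zero (method-of-moments fallback)",
            RuntimeWarning,
        )
        sigma_u2 = 0.0

    se_contrast = float(np.sqrt(2.0 * sigma_e2 / (n * r)))
    rows = []
    for a, b in itertools.combinations(levels, 2):
        est = float(lvl_means[a] - lvl_means[b])
        if se_contrast == 0:
            z = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
        else:
            z = est / se_contrast
            p = 2.0 * stats.t.sf(abs(z), df_resid)
        p_bonf = min(1.0, p * n_comparisons)
        rows.append(
            {
                "contrast": f"{a}-{b}",
                "estimate": est,
                "se": se_contrast,
                "z": float(z),
                "p": float(p),
                "p_bonferroni": float(p_bonf),
                "significant": bool(p < alpha),
            }
        )
    return MixedModelResult(
        fixed_effects=pd.DataFrame(rows),
        variance_components={"subject_var": float(sigma_u2), "residual_var": float(sigma_e2)},
        level_means={lvl: float(m) for lvl, m in lvl_means.items()},
        alpha=alpha,
        residual_df=float(df_resid),
    )
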