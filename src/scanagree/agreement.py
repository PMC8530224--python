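"""Volumetric agreement statistics and the study aggregation scheme.

Per-subject pair metrics (CV, absolute volume difference, percentual
difference), intraclass correlation with absolute-agreement/single-measure
two-way form and F-based confidence intervals, and the intra-/inter-scanner
summary tables with an unweighted "all volumes" row across structures.

Conventions:

- sample SD (n-1 denominator) throughout, including two-value CVs — this is
  what makes the percentual difference exactly sqrt(2) times the pair CV;
- inter-scanner metrics operate on the per-scanner mean of the two
  repetitions, then compare scanners pairwise or jointly;
- the "all volumes" summary is the unweighted mean (and SD) across the
  per-structure means, never the pooled subject-level mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import VolumeRecord, records_to_frame

__all__ = [
    "cv_percent",
    "avd",
    "percentual_difference",
    "ICCResult",
    "icc_absolute_single",
    "classify_icc",
    "pooled_group_stats",
    "PairAgreement",
    "AgreementTable",
    "summarize_agreement",
    "aggregate_structure_means",
    "ALL_VOLUMES",
    "ALL_SCANNERS",
]

ALL_VOLUMES = "all_volumes"
ALL_SCANNERS = "all_scanners"


def cv_percent(values) -> float:
    """Coefficient of variation: sample SD over mean, x100 (%)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(x.std(ddof=1) / mean * 100.0)


def avd(a: float, b: float) -> float:
    """Absolute volume difference (mL) between test and retest."""
    if a <= 0 or b <= 0:
        raise ValueError("volumes must be positive")
    return abs(float(a) - float(b))


def percentual_difference(a: float, b: float) -> float:
    """|a - b| as a percentage of the pair mean.

    For any two measurements this is exactly sqrt(2) times their CV.
    """
    mean = (float(a) + float(b)) / 2.0
    if mean <= 0:
        raise ValueError("percentual difference undefined for non-positive mean")
    return abs(float(a) - float(b)) / mean * 100.0


@dataclass
class PairAgreement:
    """Agreement metrics for one subject's measurement pair."""

    cv_percent: float
    avd: float
    pd_percent: float
    dsc: float | None = None


@dataclass
class ICCResult:
    """Absolute-agreement single-measure ICC with a 95% F-based interval."""

    estimate: float
    ci_low: float
    ci_high: float
    mean_squares: tuple  # (rows, columns, error)
    classification: str
    one_way_estimate: float
    n_subjects: int
    n_conditions: int
    #: classification of the CI lower bound, the conservative reading
    ci_classification: str = ""


def classify_icc(estimate: float) -> str:
    """Reliability band of an ICC point estimate.

    poor < 0.50 <= moderate < 0.75 <= good < 0.90 <= excellent.
    """
    if not -1.0 <= estimate <= 1.0 + 1e-12:
        raise ValueError("ICC estimate outside [-1, 1]")
    if estimate < 0.50:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.90:
        return "good"
    return "excellent"


def _two_way_mean_squares(matrix: np.ndarray) -> tuple[float, float, float]:
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = matrix - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err)


def icc_absolute_single(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    ``matrix`` is subjects x conditions (complete and balanced; no
    imputation).  The estimate is

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with the 95% CI from the F-distribution with Satterthwaite degrees of
    freedom.  The one-way variance-component form SA^2/(SA^2+SW^2) is
    returned as a diagnostic.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects x conditions matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >=3 subjects and >=2 conditions")
    if np.isnan(x).any():
        raise ValueError("matrix is incomplete; ICC requires a balanced design")

    ms_r, ms_c, ms_e = _two_way_mean_squares(x)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    estimate = 0.0 if denom == 0 else (ms_r - ms_e) / denom
    estimate = float(np.clip(estimate, -1.0, 1.0))

    # one-way decomposition: SA^2 = (MS_between - MS_within)/k, SW^2 = MS_within
    row_means = x.mean(axis=1)
    ms_within = float(np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1)))
    one_way_denom = ms_r + (k - 1) * ms_within
    one_way = 0.0 if one_way_denom == 0 else (ms_r - ms_within) / one_way_denom
    one_way = float(np.clip(one_way, -1.0, 1.0))

    ci_low, ci_high = _icc_a1_confint(ms_r, ms_c, ms_e, n, k, estimate, alpha)
    return ICCResult(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        mean_squares=(ms_r, ms_c, ms_e),
        classification=classify_icc(estimate),
        one_way_estimate=one_way,
        n_subjects=n,
        n_conditions=k,
        ci_classification=classify_icc(max(ci_low, -1.0)),
    )


def _icc_a1_confint(ms_r, ms_c, ms_e, n, k, icc, alpha) -> tuple[float, float]:
    if ms_e == 0 and ms_c == 0:
        # perfect agreement: degenerate interval
        return (1.0, 1.0) if icc == 1.0 else (icc, icc)
    if icc >= 1:
        return (icc, icc)
    # Satterthwaite df for the denominator of the F ratio
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    vd = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    if vd == 0:
        return (icc, icc)
    v = (a * ms_c + b * ms_e) ** 2 / vd
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    denom_l = f_upper * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
    denom_u = k * ms_c + (k * n - k - n) * ms_e + n * f_lower * ms_r
    low = n * (ms_r - f_upper * ms_e) / denom_l if denom_l != 0 else icc
    high = n * (f_lower * ms_r - ms_e) / denom_u if denom_u != 0 else icc
    low = float(np.clip(low, -1.0, 1.0))
    high = float(np.clip(high, -1.0, 1.0))
    return min(low, icc), max(high, icc)


def pooled_group_stats(groups) -> tuple[float, float]:
    """Pool (n, mean, sd) summaries into one (mean, sd).

    The pooled SD combines within-group sums of squares (n-1 convention)
    with between-group dispersion, divided by (sum n) - 1; it equals the SD
    of the concatenated sample.
    """
    groups = list(groups)
    total_n = sum(g[0] for g in groups)
    if total_n < 2:
        raise ValueError("pooled SD needs at least two observations")
    for n, _, sd in groups:
        if n < 1 or sd < 0:
            raise ValueError("invalid group summary")
    pooled_mean = sum(n * m for n, m, _ in groups) / total_n
    ss = sum((n - 1) * sd**2 + n * (m - pooled_mean) ** 2 for n, m, sd in groups)
    return float(pooled_mean), float(np.sqrt(ss / (total_n - 1)))


def aggregate_structure_means(values) -> tuple[float, float]:
    """Unweighted mean and sample SD across per-structure summary values."""
    x = np.asarray(list(values), dtype=float)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


@dataclass
class AgreementTable:
    """Per-structure, per-comparison agreement summary.

    ``data`` has one row per (structure, comparison) plus an
    ``all_volumes`` row per comparison whose mean columns are the unweighted
    means of the per-structure means (SD across structures).
    """

    data: pd.DataFrame
    icc_results: dict = field(default_factory=dict)
    mode: str = "intra"

    def row(self, structure: str, comparison: str) -> pd.Series:
        sel = self.data[
            (self.data["structure"] == structure) & (self.data["comparison"] == comparison)
        ]
        if sel.empty:
            raise KeyError((structure, comparison))
        return sel.iloc[0]


def _validate_complete(df: pd.DataFrame) -> None:
    key = ["subject_id", "scanner_id", "repetition", "structure"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate measurement keys: {df[dup][key].values.tolist()[:5]}")
    subjects = df["subject_id"].unique()
    scanners = df["scanner_id"].unique()
    reps = df["repetition"].unique()
    structures = df["structure"].unique()
    expected = {
        (su, sc, int(r), st)
        for su in subjects
        for sc in scanners
        for r in reps
        for st in structures
    }
    present = set(map(tuple, df[key].itertuples(index=False, name=None)))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"incomplete design; missing cells (first 5): {missing[:5]}")


def _pair_metrics(values: np.ndarray) -> tuple[float, float, float]:
    cv = cv_percent(values)
    if values.size == 2:
        return cv, avd(values[0], values[1]), percentual_difference(values[0], values[1])
    return cv, np.nan, np.nan


def _summary_rows(per_subject: pd.DataFrame, structure, comparison, icc_res, dsc_values):
    row = {
        "structure": structure,
        "comparison": comparison,
        "n_subjects": len(per_subject),
        "cv_mean": per_subject["cv"].mean(),
        "cv_sd": per_subject["cv"].std(ddof=1),
        "avd_mean": per_subject["avd"].mean(),
        "avd_sd": per_subject["avd"].std(ddof=1),
        "pd_mean": per_subject["pd"].mean(),
        "pd_sd": per_subject["pd"].std(ddof=1),
        "icc": icc_res.estimate,
        "icc_ci_low": icc_res.ci_low,
        "icc_ci_high": icc_res.ci_high,
        "icc_class": icc_res.classification,
    }
    if dsc_values is not None and len(dsc_values):
        row["dsc_mean"] = float(np.mean(dsc_values))
        row["dsc_sd"] = float(np.std(dsc_values, ddof=1)) if len(dsc_values) > 1 else 0.0
    else:
        row["dsc_mean"] = np.nan
        row["dsc_sd"] = np.nan
    return row


def _lookup_dsc(dscs: pd.DataFrame | None, structure, comparison):
    if dscs is None:
        return None
    sel = dscs[(dscs["structure"] == structure) & (dscs["comparison"] == comparison)]
    return sel["dsc"].to_numpy() if not sel.empty else None


def summarize_agreement(
    records: list[VolumeRecord] | pd.DataFrame,
    dscs: pd.DataFrame | None = None,
    mode: str = "intra",
) -> AgreementTable:
    """Build a per-structure agreement table in one of three modes.

    intra
        per scanner: CV/AVD/PD between the two repetitions of each subject,
        ICC over the subjects x repetitions matrix.
    inter
        per scanner pair: metrics on the per-scanner means of the two
        repetitions, ICC over subjects x 2 scanner means.
    all_scanner
        one joint comparison across all scanners' per-scanner means; AVD and
        PD are omitted (they only allow pairwise comparisons).

    ``dscs``, when given, is a long DataFrame with columns
    (subject_id, comparison, structure, dsc).
    """
    if mode not in ("intra", "inter", "all_scanner"):
        raise ValueError(f"unknown mode {mode!r}")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    _validate_complete(df)
    structures = list(df["structure"].unique())
    scanners = list(df["scanner_id"].unique())
    subjects = sorted(df["subject_id"].unique())

    rows = []
    icc_results: dict = {}

    def add_comparison(comparison: str, matrix_by_structure):
        for structure in structures:
            matrix = matrix_by_structure(structure)  # subjects x conditions
            per_subject = pd.DataFrame(
                [dict(zip(("cv", "avd", "pd"), _pair_metrics(matrix[i]))) for i in range(len(matrix))]
            )
            icc_res = icc_absolute_single(matrix)
            icc_results[(structure, comparison)] = icc_res
            rows.append(
                _summary_rows(per_subject, structure, comparison, icc_res, _lookup_dsc(dscs, structure, comparison))
            )

    if mode == "intra":
        for scanner in scanners:
            sub = df[df["scanner_id"] == scanner]
            pivots = {
                st: sub[sub["structure"] == st]
                .pivot(index="subject_id", columns="repetition", values="volume_ml")
                .loc[subjects]
                .to_numpy()
                for st in structures
            }
            add_comparison(scanner, lambda st, p=pivots: p[st])
    else:
        # per-subject per-scanner mean of the repetitions
        means = (
            df.groupby(["subject_id", "scanner_id", "structure"], sort=False)["volume_ml"]
            .mean()
            .reset_index()
        )
        def scanner_matrix(structure, scanner_subset):
            sub = means[means["structure"] == structure]
            pivot = sub.pivot(index="subject_id", columns="scanner_id", values="volume_ml")
            return pivot.loc[subjects, list(scanner_subset)].to_numpy()

        if mode == "inter":
            for pair in itertools.combinations(scanners, 2):
                label = f"{pair[0]}-{pair[1]}"
                add_comparison(label, lambda st, p=pair: scanner_matrix(st, p))
        else:
            if len(scanners) < 3:
                raise ValueError("all_scanner mode needs at least three scanners")
            add_comparison(ALL_SCANNERS, lambda st: scanner_matrix(st, scanners))

    table = pd.DataFrame(rows)

    # unweighted all-volumes summary per comparison
    summary_rows = []
    for comparison, group in table.groupby("comparison", sort=False):
        row = {"structure": ALL_VOLUMES, "comparison": comparison, "n_subjects": int(group["n_subjects"].iloc[0])}
        for metric in ("cv", "avd", "pd", "dsc"):
            col = f"{metric}_mean"
            vals = group[col].dropna()
            if vals.empty:
                row[col], row[f"{metric}_sd"] = np.nan, np.nan
            else:
                row[col], row[f"{metric}_sd"] = aggregate_structure_means(vals)
        row["icc"] = group["icc"].mean()
        row["icc_ci_low"] = group["icc_ci_low"].mean()
        row["icc_ci_high"] = group["icc_ci_high"].mean()
        row["icc_class"] = classify_icc(float(row["icc"]))
        summary_rows.append(row)
    table = pd.concat([table, pd.DataFrame(summary_rows)], ignore_index=True)
    return AgreementTable(data=table, icc_results=icc_results, mode=mode)
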