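"""Readers, writers and the study report builder.

Assembles the full agreement study output from a long-format volume table
(and optionally phantom image pairs): intra-/inter-scanner agreement tables,
percentual-difference table, actual-volume summaries, pooled demographics,
Bland-Altman results with clinical acceptability, and the scanner-effect
mixed models.  All tables are written as CSV (values rounded at
serialization only) and as full-precision JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import published
from .agreement import (
    ALL_SCANNERS,
    AgreementTable,
    pooled_group_stats,
    summarize_agreement,
)
from .records import REQUIRED_COLUMNS, VolumeRecord, frame_to_records, records_to_frame
from .reliability import (
    AcceptabilityRule,
    BAResult,
    acceptability,
    bland_altman,
    fit_scanner_effect_model,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "load_volume_table",
    "write_volume_table",
    "build_report",
]

logger = logging.getLogger("scanagree")

_ROUND_CSV = {"cv": 2, "pd": 2, "dsc": 2, "avd": 2, "icc": 3}


@dataclass
class StudyConfig:
    """Configuration of one agreement study analysis."""

    structures: tuple = published.STRUCTURES
    structure_class: dict = field(default_factory=lambda: dict(published.STRUCTURE_CLASS))
    scanners: tuple = published.SCANNERS
    nmi_bins: int = 32
    alpha: float = 0.005
    n_structures_bonferroni: int = 11
    demographic_groups: dict = field(
        default_factory=lambda: dict(published.DEMOGRAPHIC_GROUPS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.structures)) != len(self.structures):
            raise ValueError("structure names must be unique")
        missing = [s for s in self.structures if s not in self.structure_class]
        if missing:
            raise ValueError(f"structure classes missing for: {missing}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All study tables plus patient-level and model results."""

    intra_table: AgreementTable
    inter_table: AgreementTable
    all_scanner_table: AgreementTable | None
    pd_table: pd.DataFrame
    actual_volumes_table: pd.DataFrame
    demographics: pd.DataFrame
    ba_results: dict  # (structure, scanner) -> (BAResult, AcceptabilityReport)
    model_results: dict  # structure -> MixedModelResult (actual volumes)
    config_hash: str
    image_metrics_table: pd.DataFrame | None = None


def load_volume_table(path) -> list[VolumeRecord]:
    """Read and validate a long-format volume CSV.

    Raises a descriptive error (with row numbers) for missing columns,
    duplicate (subject, scanner, repetition, structure) keys and
    non-positive volumes.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df.index[~(pd.to_numeric(df["volume_ml"], errors="coerce") > 0)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: non-positive or non-numeric volume at row(s) {[i + 2 for i in bad[:5]]}")
    key = ["subject_id", "scanner_id", "repetition", "structure"]
    dup = df.index[df.duplicated(subset=key)]
    if len(dup):
        raise ValueError(f"{path}: duplicate measurement key at row(s) {[i + 2 for i in dup[:5]]}")
    return frame_to_records(df)


def write_volume_table(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _percentual_table(intra: AgreementTable, inter: AgreementTable) -> pd.DataFrame:
    """Wide percentual-difference table: structures x comparisons."""
    frames = []
    for table in (intra, inter):
        sub = table.data[["structure", "comparison", "pd_mean", "pd_sd"]].copy()
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot(index="structure", columns="comparison", values="pd_mean")
    return wide


def _actual_volumes(df: pd.DataFrame, scanners) -> pd.DataFrame:
    rows = []
    for structure, group in df.groupby("structure", sort=False):
        row = {"structure": structure}
        for scanner in scanners:
            vals = group.loc[group["scanner_id"] == scanner, "volume_ml"]
            row[f"{scanner}_mean"] = vals.mean()
            row[f"{scanner}_sd"] = vals.std(ddof=1)
        row["all_mean"] = group["volume_ml"].mean()
        row["all_sd"] = group["volume_ml"].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _demographics(groups: dict) -> pd.DataFrame:
    rows = [
        {"group": name, "n": n, "age_mean": m, "age_sd": sd}
        for name, (n, m, sd) in groups.items()
    ]
    pooled_mean, pooled_sd = pooled_group_stats(groups.values())
    rows.append(
        {
            "group": "total",
            "n": sum(n for n, _, _ in groups.values()),
            "age_mean": pooled_mean,
            "age_sd": pooled_sd,
        }
    )
    return pd.DataFrame(rows)


def build_report(
    config: StudyConfig,
    volumes: list[VolumeRecord] | pd.DataFrame,
    dscs: pd.DataFrame | None = None,
    image_metrics_table: pd.DataFrame | None = None,
    out_dir=None,
) -> StudyReport:
    """Run the full statistical analysis and optionally write all outputs.

    Deterministic for a fixed config and input table; the config hash is
    recorded in the report and in the JSON output.
    """
    t0 = time.perf_counter()
    df = volumes if isinstance(volumes, pd.DataFrame) else records_to_frame(volumes)
    logger.info("report: %d measurements, %d structures", len(df), df["structure"].nunique())

    intra = summarize_agreement(df, dscs=dscs, mode="intra")
    inter = summarize_agreement(df, dscs=dscs, mode="inter")
    # the joint all-scanner comparison needs three or more scanners
    all_sc = (
        summarize_agreement(df, dscs=dscs, mode="all_scanner")
        if df["scanner_id"].nunique() >= 3
        else None
    )
    logger.info("report: agreement tables done (%.2fs)", time.perf_counter() - t0)

    scanners = list(df["scanner_id"].unique())
    actual = _actual_volumes(df, scanners)

    # Bland-Altman per structure per scanner on the repetition pairs
    ba_results = {}
    for structure in df["structure"].unique():
        for scanner in scanners:
            sub = df[(df["structure"] == structure) & (df["scanner_id"] == scanner)]
            pivot = sub.pivot(index="subject_id", columns="repetition", values="volume_ml")
            pairs = pivot.to_numpy()[:, :2]
            res = bland_altman(pairs, subject_ids=list(pivot.index))
            rule = AcceptabilityRule(
                structure_class=config.structure_class.get(structure, "large")
            )
            report = acceptability(res, float(pairs.mean()), rule)
            ba_results[(structure, scanner)] = (res, report)
    logger.info("report: Bland-Altman done (%.2fs)", time.perf_counter() - t0)

    # scanner-effect mixed model on actual volumes, per structure
    model_results = {}
    long = df.rename(columns={"scanner_id": "level", "volume_ml": "value"})
    for structure in df["structure"].unique():
        sub = long[long["structure"] == structure]
        model_results[structure] = fit_scanner_effect_model(
            sub,
            alpha=config.alpha,
            n_comparisons=config.n_structures_bonferroni,
        )
    logger.info("report: mixed models done (%.2fs)", time.perf_counter() - t0)

    report = StudyReport(
        intra_table=intra,
        inter_table=inter,
        all_scanner_table=all_sc,
        pd_table=_percentual_table(intra, inter),
        actual_volumes_table=actual,
        demographics=_demographics(config.demographic_groups),
        ba_results=ba_results,
        model_results=model_results,
        config_hash=config.config_hash(),
        image_metrics_table=image_metrics_table,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _round_for_csv(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        for prefix, ndigits in _ROUND_CSV.items():
            if str(col).startswith(prefix):
                out[col] = out[col].astype(float).round(ndigits)
    return out


def write_report(report: StudyReport, out_dir) -> None:
    """Write every table as CSV (rounded) and the full report as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "intra_agreement": report.intra_table.data,
        "inter_agreement": report.inter_table.data,
        "actual_volumes": report.actual_volumes_table,
        "demographics": report.demographics,
    }
    if report.all_scanner_table is not None:
        tables["all_scanner_agreement"] = report.all_scanner_table.data
    for name, df in tables.items():
        _round_for_csv(df).to_csv(out / f"{name}.csv", index=False)
    report.pd_table.round(2).to_csv(out / "percentual_differences.csv")
    if report.image_metrics_table is not None:
        report.image_metrics_table.to_csv(out / "image_metrics.csv", index=False)

    ba_rows = []
    for (structure, scanner), (res, acc) in report.ba_results.items():
        ba_rows.append(
            {
                "structure": structure,
                "scanner": scanner,
                "bias": res.bias,
                "sd_diff": res.sd_diff,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "n_outliers": len(res.outliers),
                "accepted": acc.accepted,
                "max_allowed_percent": acc.max_allowed_percent,
            }
        )
    pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False)

    # plot-ready Bland-Altman point data for external plotting
    point_rows = []
    for (structure, scanner), (res, _) in report.ba_results.items():
        for sid, mean, diff in zip(res.subject_ids, res.means, res.differences):
            point_rows.append(
                {
                    "structure": structure,
                    "scanner": scanner,
                    "subject_id": sid,
                    "mean": mean,
                    "difference": diff,
                }
            )
    pd.DataFrame(point_rows).to_csv(out / "bland_altman_points.csv", index=False)

    model_rows = []
    for structure, res in report.model_results.items():
        for row in res.fixed_effects.to_dict("records"):
            model_rows.append({"structure": structure, **row})
    pd.DataFrame(model_rows).to_csv(out / "scanner_effects.csv", index=False)

    payload = {
        "config_hash": report.config_hash,
        "tables": {name: json.loads(df.to_json(orient="records")) for name, df in tables.items()},
        "bland_altman": ba_rows,
        "scanner_effects": model_rows,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    logger.info("report written to %s (config %s)", out, report.config_hash)
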