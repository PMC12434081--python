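"""End-to-end studies: criterion attachment, QC, accuracy and dilatation runs.

Two entry points mirror the two study questions:

* :func:`run_accuracy_study` — Grubbs QC on the criterion BSA distribution,
  then the per-sex equation-vs-criterion comparison with RMSE ranking;
* :func:`run_dilatation_study` — BSA-indexed echo measures, dilatation calls
  under every equation's normalization, prevalence and McNemar contrasts,
  plus a single-subject worked-example mode.

Reports keep full precision in their JSON form; rounding (3 decimals for m²,
1 decimal for indexed echo values) happens only when rendering CSV tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .comparison import ComparisonReport, compare_equations
from .echo import (
    CutPoints,
    DEFAULT_CUTPOINTS,
    DilatationReport,
    EchoMeasurements,
    classify_subject,
    normalize_echo,
    prevalence_by_method,
)
from .equations import METHOD_IDS, Subject, predict_all
from .mesh import GrubbsResult, ScanPair, average_replicates, grubbs_outliers, load_mesh

logger = logging.getLogger("bsaecho")

__all__ = [
    "attach_criterion",
    "run_accuracy_study",
    "run_dilatation_study",
    "AccuracyStudy",
    "worked_example",
    "accuracy_table",
    "dilatation_table",
]


def attach_criterion(
    cohort: pd.DataFrame,
    mesh_dir: Optional[str] = None,
    mesh_scale: float = 1.0,
) -> pd.DataFrame:
    """Ensure the cohort carries a ``criterion_bsa_m2`` column.

    Accepted sources, in order of preference: an existing
    ``criterion_bsa_m2`` column; replicate scan areas
    (``scan1_bsa_m2``/``scan2_bsa_m2``); mesh files
    (``mesh_path_1``/``mesh_path_2``, resolved against ``mesh_dir``) whose
    triangle areas are summed and the replicates averaged.
    """
    from pathlib import Path

    from .mesh import mesh_surface_area

    if "criterion_bsa_m2" in cohort.columns:
        return cohort
    out = cohort.copy()
    if "scan1_bsa_m2" in cohort.columns:
        scan_cols = [c for c in ("scan1_bsa_m2", "scan2_bsa_m2") if c in cohort.columns]
        out["criterion_bsa_m2"] = [
            average_replicates(ScanPair(str(r["id"]), [r[c] for c in scan_cols if pd.notna(r[c])]))
            for _, r in cohort.iterrows()
        ]
        return out
    if "mesh_path_1" in cohort.columns:
        base = Path(mesh_dir) if mesh_dir else Path(".")
        mesh_cols = [c for c in ("mesh_path_1", "mesh_path_2") if c in cohort.columns]
        criterion = []
        for _, r in cohort.iterrows():
            areas = [
                mesh_surface_area(load_mesh(base / r[c], scale=mesh_scale))
                for c in mesh_cols
                if pd.notna(r[c])
            ]
            criterion.append(average_replicates(ScanPair(str(r["id"]), areas)))
        out["criterion_bsa_m2"] = criterion
        return out
    raise ValueError(
        "no criterion source: need criterion_bsa_m2, scan*_bsa_m2 or mesh_path_* columns"
    )


@dataclass
class AccuracyStudy:
    qc: GrubbsResult
    excluded_ids: list
    by_sex: dict  # sex -> ComparisonReport

    def rank_by_rmse(self, sex: str) -> list:
        return self.by_sex[sex].rank_by_rmse()

    def to_dict(self) -> dict:
        return {
            "qc": self.qc.to_dict(),
            "excluded_ids": self.excluded_ids,
            "by_sex": {s: r.to_dict() for s, r in self.by_sex.items()},
        }


def run_accuracy_study(
    cohort: pd.DataFrame,
    grubbs_alpha: float = 0.05,
    alpha: float = 0.05,
    mesh_dir: Optional[str] = None,
    mesh_scale: float = 1.0,
) -> AccuracyStudy:
    """Equation-accuracy study on a cohort with a criterion BSA source.

    Grubbs' iterative outlier screen (two-sided, ``grubbs_alpha``) runs on
    the pooled criterion BSA distribution as preprocessing QC; flagged
    subjects are excluded and logged. Each sex present with at least three
    subjects then gets the full comparison table.
    """
    cohort = attach_criterion(cohort, mesh_dir=mesh_dir, mesh_scale=mesh_scale)
    qc = grubbs_outliers(cohort["criterion_bsa_m2"].to_numpy(dtype=float), grubbs_alpha)
    excluded = [str(cohort.iloc[i]["id"]) for i in qc.flagged_indices]
    if excluded:
        logger.info("Grubbs QC flagged %d subject(s): %s", len(excluded), excluded)
        cohort = cohort.drop(cohort.index[qc.flagged_indices])
    else:
        logger.info("Grubbs QC flagged no subjects")

    by_sex = {}
    for sex in ("male", "female"):
        n = int((cohort["sex"] == sex).sum())
        if n >= 3:
            report = compare_equations(cohort, sex=sex, alpha=alpha)
            logger.info(
                "%s (n=%d): omnibus branch %s, best RMSE %s",
                sex,
                n,
                report.omnibus["branch"],
                report.rank_by_rmse()[0],
            )
            by_sex[sex] = report
        elif n:
            logger.warning("skipping %s: only %d subject(s) (<3)", sex, n)
    if not by_sex:
        raise ValueError("no sex stratum has at least 3 subjects")
    return AccuracyStudy(qc=qc, excluded_ids=excluded, by_sex=by_sex)


def run_dilatation_study(
    cohort: pd.DataFrame, cutpoints: CutPoints = DEFAULT_CUTPOINTS
) -> DilatationReport:
    """Dilatation-prevalence study across all ten BSA normalizations."""
    report = prevalence_by_method(cohort, cutpoints)
    logger.info(
        "dilatation prevalence range across normalizations: %.1f%% - %.1f%%",
        report.prevalence_table["prevalence_pct"].min(),
        report.prevalence_table["prevalence_pct"].max(),
    )
    return report


def worked_example(
    subject: Subject,
    echo: EchoMeasurements,
    cutpoints: CutPoints = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Single-subject mode: per-equation BSA, indexed values and calls.

    Returns one row per equation with the BSA estimate, the three indexed
    echo values, and the left/right/counted dilatation flags — the per-method
    classification a clinician would see for this athlete.
    """
    rows = []
    for method, bsa in predict_all(subject).items():
        call = classify_subject(echo, bsa, subject.sex, cutpoints, subject.id, method)
        rows.append(
            {
                "method_id": method,
                "bsa_m2": bsa,
                "lvedd_rel": normalize_echo(echo.lvedd_mm, bsa),
                "lvedv_rel": normalize_echo(echo.lvedv_ml, bsa),
                "rvbd_rel": normalize_echo(echo.rvbd_mm, bsa),
                "left": call.left,
                "right": call.right,
                "counted": call.counted,
            }
        )
    return pd.DataFrame(rows).set_index("method_id")


def accuracy_table(report: ComparisonReport, decimals: int = 3) -> pd.DataFrame:
    """Render one sex's comparison report as a rounded publication-style table."""
    t = report.table.copy()
    t["median_iqr_m2"] = [
        f"{r.est_median:.{decimals}f} ({r.est_q1:.{decimals}f}-{r.est_q3:.{decimals}f})"
        for r in t.itertuples()
    ]
    t["bias_sd_pct"] = [
        f"{r.bias_pct:.1f} ± {r.sd_diff_pct:.1f}" for r in t.itertuples()
    ]
    out = t[["median_iqr_m2", "pcc", "rmse", "bias_sd_pct", "p_vs_criterion"]].copy()
    out["pcc"] = out["pcc"].round(3)
    out["rmse"] = out["rmse"].round(decimals)
    return out


def dilatation_table(report: DilatationReport) -> pd.DataFrame:
    """Render the dilatation report as a rounded publication-style table."""
    rel = report.relative_summary
    rows = []
    for method in METHOD_IDS:
        row = {"method_id": method}
        for var in ("lvedd_mm", "lvedv_ml", "rvbd_mm"):
            for sex in ("male", "female"):
                key = (method, var, sex)
                if key in rel.index:
                    s = rel.loc[key]
                    row[f"{var.split('_')[0]}_rel_{sex}"] = (
                        f"{s['median']:.1f} ({s['q1']:.1f}-{s['q3']:.1f})"
                    )
        prev = report.prevalence_table.loc[method]
        row["prevalence"] = (
            f"{int(prev['counted'])}/{int(prev['total'])} ({prev['prevalence_pct']:.1f}%)"
        )
        row["left_right_cases"] = f"{int(prev['left_only'])} ({int(prev['right_only'])})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("method_id")


def save_report(obj, path) -> None:
    """Write any report object exposing ``to_dict`` as full-precision JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj.to_dict() if hasattr(obj, "to_dict") else obj, fh, indent=2, default=_default)
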