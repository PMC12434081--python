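"""BSA-indexed echocardiographic measures and ventricular-dilatation calls.

Absolute echo measures — left ventricular end-diastolic diameter (LVEDD, mm)
and volume (LVEDV, ml), right ventricular basal diameter (RVBD, mm) — are
divided by BSA (m²) to give relative indexes. Dilatation is called against
sex-specific cut-points (strictly "above"):

* left:  LVEDD/BSA > 30 mm/m² (male) / 31 (female), or
         LVEDV/BSA > 74 ml/m² (male) / 61 (female)
* right: RVBD/BSA  > 22 mm/m² (both sexes)

Subjects dilated on BOTH sides are excluded from the prevalence numerator
(but kept in the denominator): balanced biventricular enlargement is the
expected physiological remodelling of the athlete's heart, not pathology.
Prevalences under two different BSA normalizations are compared with
McNemar's paired-proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .equations import METHOD_IDS, SEXES, Subject, predict_all

__all__ = [
    "EchoMeasurements",
    "CutPoints",
    "DilatationCall",
    "DEFAULT_CUTPOINTS",
    "normalize_echo",
    "classify_subject",
    "classify_cohort",
    "prevalence",
    "PrevalenceResult",
    "mcnemar_paired",
    "McNemarResult",
    "prevalence_by_method",
    "DilatationReport",
]

ECHO_COLUMNS = ("lvedd_mm", "lvedv_ml", "rvbd_mm")


@dataclass
class EchoMeasurements:
    lvedd_mm: float
    lvedv_ml: float
    rvbd_mm: float

    def __post_init__(self) -> None:
        for name in ECHO_COLUMNS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CutPoints:
    """Dilatation cut-points on the BSA-indexed values (guideline defaults)."""

    lvedd: dict = field(default_factory=lambda: {"male": 30.0, "female": 31.0})
    lvedv: dict = field(default_factory=lambda: {"male": 74.0, "female": 61.0})
    rvbd: float = 22.0

    def __post_init__(self) -> None:
        values = list(self.lvedd.values()) + list(self.lvedv.values()) + [self.rvbd]
        if any(v <= 0 for v in values):
            raise ValueError("cut-points must be positive")


DEFAULT_CUTPOINTS = CutPoints()


def normalize_echo(value: float, bsa_m2: float) -> float:
    """Relative index: absolute measure / BSA, full precision.

    Report to 1 decimal; classify on the unrounded value.
    """
    if not value > 0:
        raise ValueError("echo measurement must be strictly positive")
    if not bsa_m2 > 0:
        raise ValueError("BSA must be strictly positive (m²)")
    return value / bsa_m2


@dataclass
class DilatationCall:
    subject_id: str
    method_id: str  # the BSA source used for normalization
    left: bool
    right: bool

    @property
    def counted(self) -> bool:
        """In the prevalence numerator iff exactly one ventricle is dilated."""
        return self.left != self.right


def classify_subject(
    echo: EchoMeasurements,
    bsa_m2: float,
    sex: str,
    cutpoints: CutPoints = DEFAULT_CUTPOINTS,
    subject_id: str = "",
    method_id: str = "",
) -> DilatationCall:
    """Call left/right ventricular dilatation for one subject.

    Left is positive if either indexed LVEDD or indexed LVEDV is strictly
    above its sex-specific cut-point; right if indexed RVBD is strictly above
    the shared cut-point. Exact equality is non-dilated.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    left = (
        normalize_echo(echo.lvedd_mm, bsa_m2) > cutpoints.lvedd[sex]
        or normalize_echo(echo.lvedv_ml, bsa_m2) > cutpoints.lvedv[sex]
    )
    right = normalize_echo(echo.rvbd_mm, bsa_m2) > cutpoints.rvbd
    return DilatationCall(subject_id, method_id, bool(left), bool(right))


def classify_cohort(
    cohort: pd.DataFrame,
    bsa: np.ndarray,
    cutpoints: CutPoints = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Vectorised dilatation calls for a cohort under one BSA source.

    ``cohort`` needs ``sex`` plus the echo columns; ``bsa`` is the aligned
    per-subject BSA vector (m²). Returns a boolean frame with columns
    ``left, right, counted`` indexed like ``cohort``.
    """
    bsa = np.asarray(bsa, dtype=float)
    if np.any(bsa <= 0):
        raise ValueError("BSA values must be strictly positive")
    sex = cohort["sex"].to_numpy()
    cut_lvedd = np.where(sex == "male", cutpoints.lvedd["male"], cutpoints.lvedd["female"])
    cut_lvedv = np.where(sex == "male", cutpoints.lvedv["male"], cutpoints.lvedv["female"])
    left = (cohort["lvedd_mm"].to_numpy() / bsa > cut_lvedd) | (
        cohort["lvedv_ml"].to_numpy() / bsa > cut_lvedv
    )
    right = cohort["rvbd_mm"].to_numpy() / bsa > cutpoints.rvbd
    return pd.DataFrame(
        {"left": left, "right": right, "counted": left ^ right}, index=cohort.index
    )


@dataclass
class PrevalenceResult:
    counted: int
    total: int
    left_only: int
    right_only: int

    @property
    def fraction(self) -> float:
        return self.counted / self.total

    def formatted(self) -> str:
        """Table row style: ``29/111 (26.1%)  24 (5)``."""
        return (
            f"{self.counted}/{self.total} ({100 * self.fraction:.1f}%)"
            f"\t{self.left_only} ({self.right_only})"
        )


def prevalence(calls) -> PrevalenceResult:
    """Dilatation prevalence over one method's calls (one call per subject).

    The numerator counts subjects with exactly one dilated ventricle; the
    left-only and right-only counts sum to it. Both-dilated subjects stay in
    the denominator.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no dilatation calls supplied")
    ids = [c.subject_id for c in calls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in call list")
    left_only = sum(c.left and not c.right for c in calls)
    right_only = sum(c.right and not c.left for c in calls)
    return PrevalenceResult(left_only + right_only, len(calls), left_only, right_only)


@dataclass
class McNemarResult:
    b: int  # positive under A only
    c: int  # positive under B only
    p: float
    method: str  # "exact" or "chi2_cc"


def mcnemar_paired(flags_a, flags_b, exact_threshold: int = 25) -> McNemarResult:
    """McNemar's test on two aligned boolean classifications.

    Uses the exact two-sided binomial p on the discordant counts (b, c) when
    b + c < ``exact_threshold``, otherwise the continuity-corrected
    chi-square. Identical classifications give p = 1.
    """
    a = np.asarray(flags_a, dtype=bool)
    bvec = np.asarray(flags_b, dtype=bool)
    if a.shape != bvec.shape:
        raise ValueError("classifications must cover the same subjects")
    b = int(np.sum(a & ~bvec))
    c = int(np.sum(~a & bvec))
    n = b + c
    if n == 0:
        return McNemarResult(b, c, 1.0, "exact")
    if n < exact_threshold:
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return McNemarResult(b, c, p, "exact")
    chi2 = (abs(b - c) - 1) ** 2 / n
    return McNemarResult(b, c, float(stats.chi2.sf(chi2, 1)), "chi2_cc")


@dataclass
class DilatationReport:
    """Prevalence-by-normalization report across the registered equations."""

    n_subjects: int
    relative_summary: pd.DataFrame  # per method × sex × variable: median/IQR
    prevalence_table: pd.DataFrame  # per method: prevalence + left/right split
    mcnemar_p: pd.DataFrame  # methods × methods p-values on counted flags
    sex_comparisons: pd.DataFrame  # Mann–Whitney male-vs-female p-values
    calls: dict  # method_id -> boolean frame (left, right, counted)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "relative_summary": self.relative_summary.reset_index().to_dict("records"),
            "prevalence": self.prevalence_table.reset_index().to_dict("records"),
            "mcnemar_p": self.mcnemar_p.to_dict(),
            "sex_comparisons": self.sex_comparisons.reset_index().to_dict("records"),
        }


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def prevalence_by_method(
    cohort: pd.DataFrame,
    cutpoints: CutPoints = DEFAULT_CUTPOINTS,
) -> DilatationReport:
    """Full dilatation analysis of a cohort under all ten BSA normalizations.

    ``cohort`` needs ``id, sex, weight_kg, height_cm`` and the echo columns
    ``lvedd_mm, lvedv_ml, rvbd_mm``. For each equation the cohort's echo
    measures are indexed by that equation's BSA, summarised per sex
    (median/IQR), classified, and the counted prevalences are cross-compared
    with McNemar's test. Male-vs-female contrasts of absolute and relative
    values use the Mann–Whitney U test.
    """
    missing = [c for c in ECHO_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing echo columns: {missing}")
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort")

    bsa_by_method = {}
    for method in METHOD_IDS:
        bsa_by_method[method] = np.array(
            [
                predict_all(
                    Subject(str(r["id"]), r["sex"], float(r["weight_kg"]), float(r["height_cm"]))
                )[method]
                for _, r in cohort.iterrows()
            ]
        )

    male = cohort["sex"].to_numpy() == "male"
    summary_rows = []
    prevalence_rows = []
    calls = {}
    for method in METHOD_IDS:
        bsa = bsa_by_method[method]
        flags = classify_cohort(cohort, bsa, cutpoints)
        calls[method] = flags
        left_only = int((flags["left"] & ~flags["right"]).sum())
        right_only = int((flags["right"] & ~flags["left"]).sum())
        prevalence_rows.append(
            {
                "method_id": method,
                "counted": left_only + right_only,
                "total": len(cohort),
                "prevalence_pct": 100.0 * (left_only + right_only) / len(cohort),
                "left_only": left_only,
                "right_only": right_only,
                "both": int((flags["left"] & flags["right"]).sum()),
            }
        )
        for var in ECHO_COLUMNS:
            rel = cohort[var].to_numpy() / bsa
            for sex_name, mask in (("male", male), ("female", ~male)):
                if mask.any():
                    summary_rows.append(
                        {
                            "method_id": method,
                            "variable": var,
                            "sex": sex_name,
                            **_median_iqr(rel[mask]),
                        }
                    )

    mcnemar = pd.DataFrame(np.nan, index=list(METHOD_IDS), columns=list(METHOD_IDS))
    for m_a in METHOD_IDS:
        for m_b in METHOD_IDS:
            if m_a == m_b:
                mcnemar.loc[m_a, m_b] = 1.0
            else:
                mcnemar.loc[m_a, m_b] = mcnemar_paired(
                    calls[m_a]["counted"], calls[m_b]["counted"]
                ).p

    sex_rows = []
    if male.any() and (~male).any():
        for var in ECHO_COLUMNS:
            absolute = cohort[var].to_numpy(dtype=float)
            p = float(
                stats.mannwhitneyu(absolute[male], absolute[~male]).pvalue
            )
            sex_rows.append({"variable": var, "normalization": "absolute", "p": p})
            for method in METHOD_IDS:
                rel = absolute / bsa_by_method[method]
                p = float(stats.mannwhitneyu(rel[male], rel[~male]).pvalue)
                sex_rows.append({"variable": var, "normalization": method, "p": p})
    sex_comparisons = pd.DataFrame(
        sex_rows, columns=["variable", "normalization", "p"]
    )

    return DilatationReport(
        n_subjects=len(cohort),
        relative_summary=pd.DataFrame(summary_rows).set_index(
            ["method_id", "variable", "sex"]
        ),
        prevalence_table=pd.DataFrame(prevalence_rows).set_index("method_id"),
        mcnemar_p=mcnemar,
        sex_comparisons=sex_comparisons,
        calls=calls,
    )
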