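"""Agreement statistics between predictive BSA equations and the criterion.

For each equation and sex the module computes the accuracy statistic set used
in method-comparison studies: Pearson correlation with the criterion, root
mean square error, relative bias ± SD of the relative differences (percent of
the criterion value), and Bland–Altman mean difference with 1.96·SD limits of
agreement plus a proportional-bias check (correlation of differences with
pairwise means). An omnibus across the criterion and the ten equations is run
on a normality gate: Shapiro–Wilk on the paired differences chooses between
one-way repeated-measures ANOVA and the Friedman rank test; pairwise
follow-ups against the criterion are Bonferroni-corrected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .equations import METHOD_IDS, Subject, predict_all

__all__ = [
    "rmse",
    "relative_bias_and_sd",
    "bland_altman",
    "BlandAltman",
    "pearson_r",
    "friedman_statistic",
    "friedman_test",
    "friedman_exact_p",
    "compare_equations",
    "ComparisonReport",
]


def _paired(pred, ref, min_n=1):
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be 1-D vectors of equal length")
    if len(pred) < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {len(pred)}")
    return pred, ref


def rmse(pred, ref) -> float:
    """Root mean square error sqrt(mean((pred - ref)**2)), in m²."""
    pred, ref = _paired(pred, ref, min_n=1)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def relative_bias_and_sd(pred, ref) -> tuple:
    """Mean and (n-1) SD of the per-subject relative differences, in percent.

    d_i = 100 * (pred_i - ref_i) / ref_i, with the criterion as denominator.
    """
    pred, ref = _paired(pred, ref, min_n=2)
    if np.any(ref <= 0):
        raise ValueError("criterion values must be strictly positive")
    d = 100.0 * (pred - ref) / ref
    return float(d.mean()), float(d.std(ddof=1))


@dataclass
class BlandAltman:
    mean_diff: float  # m²
    loa_low: float
    loa_high: float
    sd_diff: float
    prop_bias_r: Optional[float]  # None when differences have no spread
    prop_bias_p: Optional[float]

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(pred, ref, loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland–Altman agreement summary of pred vs ref.

    Mean difference, limits of agreement (mean ± 1.96·SD of differences), and
    the proportional-bias Pearson correlation between per-subject differences
    and per-subject means, with its two-sided p. With zero-variance
    differences the proportional-bias correlation is undefined and reported
    as absent.
    """
    pred, ref = _paired(pred, ref, min_n=3)
    diff = pred - ref
    mean = (pred + ref) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd <= 1e-14 * max(1.0, abs(md)) or np.var(mean) <= 0:
        r = p = None
    else:
        res = stats.pearsonr(diff, mean)
        r, p = float(res.statistic), float(res.pvalue)
    return BlandAltman(md, md - loa_multiplier * sd, md + loa_multiplier * sd, sd, r, p)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient; errors on zero variance."""
    x, y = _paired(x, y, min_n=3)
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _column_rank_sums(matrix: np.ndarray):
    """Within-row mid-ranks; returns (rank sums per column, tie correction)."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    return ranks.sum(axis=0), correction


def friedman_statistic(matrix) -> float:
    """Friedman chi-square statistic with mid-rank ties and tie correction.

    ``matrix`` is subjects × methods; rows are ranked independently.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 methods")
    n, k = matrix.shape
    rank_sums, correction = _column_rank_sums(matrix)
    q = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    if correction <= 0:  # all rows constant: no information, statistic 0
        return 0.0
    return q / correction


def friedman_test(matrix, exact: bool = False) -> tuple:
    """Friedman test: (chi-square statistic, p).

    ``exact=True`` replaces the asymptotic chi-square p with the exact
    permutation null (all within-row orderings equally likely); feasible only
    for small subjects × methods.
    """
    matrix = np.asarray(matrix, dtype=float)
    stat = friedman_statistic(matrix)
    if exact:
        return stat, friedman_exact_p(matrix)
    k = matrix.shape[1]
    p = float(stats.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return stat, p


def friedman_exact_p(matrix) -> float:
    """Exact permutation p for the Friedman statistic.

    Enumerates all (k!)^n assignments of each row's observed values to the
    k methods and reports the fraction with statistic >= the observed one.
    Intended for tiny problems (k! ** n enumerable).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if math.factorial(k) ** n > 2_000_000:
        raise ValueError("exact Friedman p requested for an intractable size")
    observed = friedman_statistic(matrix)
    row_perms = [
        [row[list(p)] for p in itertools.permutations(range(k))] for row in matrix
    ]
    count = total = 0
    for combo in itertools.product(*row_perms):
        total += 1
        if friedman_statistic(np.vstack(combo)) >= observed - 1e-12:
            count += 1
    return count / total


def _shapiro_p(x: np.ndarray) -> float:
    # W approximation degrades above n=5000: evenly strided subsample for the
    # branch decision only. A spread-free vector is degenerate-normal.
    if np.ptp(x) == 0:
        return 1.0
    if len(x) > 5000:
        x = x[:: int(np.ceil(len(x) / 5000))]
    return float(stats.shapiro(x).pvalue)


def _paired_t_p(d: np.ndarray) -> float:
    # Paired t against zero difference; a constant vector has zero SD, where
    # the statistic degenerates (p -> 1 for zero mean, 0 otherwise).
    if np.ptp(d) == 0:
        return 1.0 if abs(float(d.mean())) < 1e-12 else 0.0
    return float(stats.ttest_rel(d, np.zeros_like(d)).pvalue)


def _rm_anova(matrix: np.ndarray) -> tuple:
    """One-way repeated-measures ANOVA over methods (statsmodels AnovaRM)."""
    from statsmodels.stats.anova import AnovaRM

    n, k = matrix.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "method": np.tile(np.arange(k), n),
            "value": matrix.ravel(),
        }
    )
    table = AnovaRM(long, "value", "subject", within=["method"]).fit().anova_table
    return float(table["F Value"].iloc[0]), float(table["Pr > F"].iloc[0])


@dataclass
class ComparisonReport:
    """Per-sex accuracy report across the registered equations."""

    sex: Optional[str]
    n_subjects: int
    table: pd.DataFrame  # one row per method
    criterion_summary: dict  # median / quartiles of the criterion BSA
    omnibus: dict  # branch taken, statistic, p, per-method normality p

    def rank_by_rmse(self) -> list:
        return list(self.table.sort_values("rmse").index)

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "n_subjects": self.n_subjects,
            "criterion_summary": self.criterion_summary,
            "omnibus": self.omnibus,
            "methods": self.table.reset_index().to_dict(orient="records"),
        }


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def compare_equations(
    cohort: pd.DataFrame,
    sex: Optional[str] = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare every registered equation against criterion BSA for one cohort.

    Parameters
    ----------
    cohort
        DataFrame with columns ``id, sex, weight_kg, height_cm,
        criterion_bsa_m2``.
    sex
        Restrict to one sex (``"male"``/``"female"``); ``None`` uses all rows.
    alpha
        Threshold for the Shapiro–Wilk normality gate and reported tests.

    Returns
    -------
    ComparisonReport
        Per-method medians/IQRs, PCC, RMSE, bias ± SD (%), Bland–Altman
        summary, Bonferroni-corrected pairwise p vs criterion; omnibus branch
        (repeated-measures ANOVA vs Friedman) chosen by normality of the
        paired differences.
    """
    df = cohort if sex is None else cohort[cohort["sex"] == sex]
    if "criterion_bsa_m2" not in df.columns or df["criterion_bsa_m2"].isna().any():
        raise ValueError("every subject needs a criterion BSA")
    if len(df) < 3:
        raise ValueError("need at least 3 subjects with criterion BSA")

    ref = df["criterion_bsa_m2"].to_numpy(dtype=float)
    estimates = {}
    for _, row in df.iterrows():
        subj = Subject(
            str(row["id"]), row["sex"], float(row["weight_kg"]), float(row["height_cm"])
        )
        for method, value in predict_all(subj).items():
            estimates.setdefault(method, []).append(value)
    est = {m: np.asarray(v) for m, v in estimates.items()}

    normality_p = {}
    rows = []
    for method in METHOD_IDS:
        pred = est[method]
        diff = pred - ref
        normality_p[method] = _shapiro_p(diff)
        bias, sd = relative_bias_and_sd(pred, ref)
        ba = bland_altman(pred, ref)
        row = {"method_id": method}
        row.update({f"est_{k}": v for k, v in _summary(pred).items()})
        try:
            pcc = pearson_r(pred, ref)
        except ValueError:  # zero-variance cohort: correlation undefined
            pcc = float("nan")
        row.update(
            pcc=pcc,
            rmse=rmse(pred, ref),
            bias_pct=bias,
            sd_diff_pct=sd,
            ba_mean_diff=ba.mean_diff,
            ba_loa_low=ba.loa_low,
            ba_loa_high=ba.loa_high,
            prop_bias_r=ba.prop_bias_r,
            prop_bias_p=ba.prop_bias_p,
        )
        rows.append(row)

    all_normal = all(p > alpha for p in normality_p.values())
    matrix = np.column_stack([ref] + [est[m] for m in METHOD_IDS])
    if all_normal:
        branch = "repeated_measures_anova"
        try:
            statistic, p = _rm_anova(matrix)
        except Exception:  # degenerate design (e.g. identical subjects)
            statistic, p = float("nan"), float("nan")
        pairwise = {
            m: min(1.0, _paired_t_p(est[m] - ref) * len(METHOD_IDS))
            for m in METHOD_IDS
        }
    else:
        branch = "friedman"
        statistic, p = friedman_test(matrix)
        pairwise = {}
        for m in METHOD_IDS:
            d = est[m] - ref
            if np.allclose(d, 0):
                pairwise[m] = 1.0
            else:
                pairwise[m] = min(
                    1.0, float(stats.wilcoxon(d).pvalue) * len(METHOD_IDS)
                )

    table = pd.DataFrame(rows).set_index("method_id")
    table["p_vs_criterion"] = pd.Series(pairwise)

    return ComparisonReport(
        sex=sex,
        n_subjects=len(df),
        table=table,
        criterion_summary=_summary(ref),
        omnibus={
            "branch": branch,
            "statistic": statistic,
            "p": p,
            "alpha": alpha,
            "normality_p": normality_p,
        },
    )
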