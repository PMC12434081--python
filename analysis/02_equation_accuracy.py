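"""Equation-accuracy study: ten BSA equations vs the scan-derived criterion.

Reads results/cohort_imaging.csv (run 01_simulate_cohorts.py first, or point
--cohort at any cohort CSV with a criterion source), runs Grubbs QC and the
per-sex comparison, and writes the per-sex accuracy tables (median/IQR, PCC,
RMSE, bias ± SD of relative differences, Bonferroni-corrected p vs criterion)
plus a full-precision JSON report and Bland–Altman plots for the best and
worst ranked equations.
"""

import argparse
from pathlib import Path

import pandas as pd

from bsaecho.pipeline import accuracy_table, run_accuracy_study, save_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort_imaging.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(args.cohort)
    study = run_accuracy_study(cohort)
    if study.excluded_ids:
        print(f"Grubbs QC excluded {len(study.excluded_ids)} subject(s): {study.excluded_ids}")
    else:
        print("Grubbs QC: no outliers flagged")

    save_report(study, args.outdir / "accuracy_report.json")
    for sex, report in study.by_sex.items():
        table = accuracy_table(report)
        table.to_csv(args.outdir / f"accuracy_{sex}.csv")
        ranking = report.rank_by_rmse()
        print(f"\n== {sex} (n={report.n_subjects}); omnibus {report.omnibus['branch']}, "
              f"stat={report.omnibus['statistic']:.1f}, p={report.omnibus['p']:.2g} ==")
        print(table.to_string())
        print(f"RMSE ranking (best first): {', '.join(ranking)}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from bsaecho.equations import METHOD_IDS, Subject, predict_all
        from bsaecho.plots import bland_altman_plot

        for sex, report in study.by_sex.items():
            sub = cohort[cohort["sex"] == sex]
            sub = sub[~sub["id"].astype(str).isin(study.excluded_ids)]
            ref = sub["criterion_bsa_m2"].to_numpy()
            est = {m: [] for m in METHOD_IDS}
            for _, r in sub.iterrows():
                for m, v in predict_all(
                    Subject(str(r["id"]), r["sex"], r["weight_kg"], r["height_cm"])
                ).items():
                    est[m].append(v)
            best, worst = report.rank_by_rmse()[0], report.rank_by_rmse()[-1]
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            for ax, method in zip(axes, (best, worst)):
                bland_altman_plot(est[method], ref, ax=ax, label=f"{method} ({sex})")
            fig.tight_layout()
            fig.savefig(args.outdir / f"bland_altman_{sex}.png", dpi=120)
            plt.close(fig)
        print(f"\nBland–Altman plots written to {args.outdir}")
    except Exception as exc:  # plots are a convenience, not a result
        print(f"(skipping plots: {exc})")


if __name__ == "__main__":
    main()
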