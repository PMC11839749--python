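#!/usr/bin/env python
"""Statistical battery on the simulated cohort, plus recomputation of the
published comparison statistics from group summaries.

Reads results/cohort.csv; writes results/group_comparison.tsv,
results/stats_report.json and results/reference_statistics.tsv."""

import json
from pathlib import Path

import pandas as pd

from motoriiv import cohens_d_from_summaries, t_test_from_summaries
from motoriiv.reference import GROUP_SUMMARIES
from motoriiv.stats import cohort_statistics, statistics_report

ROOT = Path(__file__).resolve().parents[1]

REFERENCE_VARIANTS = {
    "iiv": "welch", "episodic_memory": "pooled", "visuospatial": "pooled",
    "processing_speed": "welch", "executive_function": "welch",
    "education_years": "pooled", "drs2": "welch", "strength_ratio": "pooled",
    "age": "pooled",
}


def main() -> None:
    cohort_path = ROOT / "results" / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit("missing upstream output: run 03_compute_iiv.py first")
    cohort = pd.read_csv(cohort_path)
    out = ROOT / "results"

    results = cohort_statistics(cohort)
    results["comparison"].to_csv(out / "group_comparison.tsv", sep="\t",
                                 index=False)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(statistics_report(results), fh, indent=2, default=float)
        fh.write("\n")

    rows = []
    for var, variant in REFERENCE_VARIANTS.items():
        s_stroke, s_healthy = GROUP_SUMMARIES[var]
        t = t_test_from_summaries(s_stroke, s_healthy, variant)
        rows.append({"variable": var, "variant": variant,
                     "t": round(t.value, 2), "df": round(float(t.df), 1),
                     "p": t.p_raw,
                     "cohens_d": round(cohens_d_from_summaries(s_stroke,
                                                               s_healthy), 2)})
    ref = pd.DataFrame(rows)
    ref.to_csv(out / "reference_statistics.tsv", sep="\t", index=False)

    anova = results["anova_iiv"]
    print("simulated cohort, Group x Sex ANOVA on IIV:")
    for eff, t in anova.items():
        print(f"  {eff}: F{t.df} = {t.value:.2f}, p = {t.p_raw:.4f}, "
              f"partial eta^2 = {t.effect_size:.3f}")
    for name in ("model_cognitive", "model_clinical"):
        if name in results:
            m = results[name]
            print(f"  {name}: R^2 = {m.r_squared:.3f}, "
                  f"F({m.df_model},{m.df_resid}) = {m.f_stat:.2f}, "
                  f"p = {m.p_model:.4f}")
    print("comparison statistics recomputed from published summaries "
          f"-> {out / 'reference_statistics.tsv'}")
    print(ref.to_string(index=False))


if __name__ == "__main__":
    main()
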