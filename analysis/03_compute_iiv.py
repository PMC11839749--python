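#!/usr/bin/env python
"""Endpoint statistic, +/-3 SD winsorization and purified IIV per
participant.

Reads scratch/features.csv and the cohort metadata; writes results/iiv.csv
(one row per participant), results/imputation_report.csv, and the joined
cohort table results/cohort.csv consumed by the statistics step."""

from pathlib import Path

import pandas as pd

from motoriiv import compute_endpoint, purify_iiv, winsorize_endpoints

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    feats_path = ROOT / "scratch" / "features.csv"
    if not feats_path.exists():
        raise SystemExit("missing upstream output: run 02_extract_features.py first")
    feats = pd.read_csv(feats_path)
    meta = pd.read_csv(ROOT / "results" / "cohort" / "metadata.csv")
    groups = meta.set_index("participant_id")["group"]

    records = compute_endpoint(feats, target_force_N=10.0, target_time_ms=180.0)
    records, report = winsorize_endpoints(records, groups)
    res = purify_iiv(records, groups, n_trials=30)

    out = ROOT / "results"
    res.per_participant.to_csv(out / "iiv.csv", index=False)
    report.to_csv(out / "imputation_report.csv", index=False)
    res.t_scores.to_csv(ROOT / "scratch" / "t_scores.csv", index=False)
    joined = meta.merge(res.per_participant[["participant_id", "iiv",
                                             "n_trials_used"]],
                        on="participant_id", validate="one_to_one")
    joined.to_csv(out / "cohort.csv", index=False)

    means = res.per_participant.groupby("group")["iiv"].agg(["mean", "std"])
    print("winsorization (one pass, group mean +/- 3 SD):")
    for r in report.itertuples():
        print(f"  {r.group}: {r.pct_imputed:.2f}% of trials imputed")
    print("purified IIV (T-score SD across 30 trials):")
    for g, row in means.iterrows():
        print(f"  {g}: mean {row['mean']:.2f}, SD {row['std']:.2f}")
    print(f"per-participant IIV and joined cohort table -> {out}")


if __name__ == "__main__":
    main()
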