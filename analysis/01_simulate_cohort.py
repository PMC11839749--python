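#!/usr/bin/env python
"""Simulate the study cohort: 66 stroke + 32 healthy participants, 30
goal-directed force-pulse trials each, aimed at 10 N in 180 ms.

Writes the participant metadata, the latent-truth sidecar and the drawn
per-trial pulse parameters under results/cohort/; the raw sampled traces
(~9M rows of force samples) go under scratch/cohort/ because they are
regenerable from the seed.
"""

import argparse
from pathlib import Path

from motoriiv import SimConfig, simulate_cohort
from motoriiv.simulate import write_latents_csv, write_metadata_csv, write_traces_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2026)
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    cohort = simulate_cohort(config, traces=True)

    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    write_metadata_csv(cohort, out / "metadata.csv")
    write_latents_csv(cohort, out / "latents.csv")

    scratch = ROOT / "scratch" / "cohort"
    scratch.mkdir(parents=True, exist_ok=True)
    cohort.trial_params.to_csv(scratch / "trial_params.csv", index=False)
    write_traces_csv(cohort, scratch / "traces.csv")

    by_group = cohort.participants.groupby("group").size()
    print(f"simulated cohort (seed {args.seed}): "
          + ", ".join(f"{n} {g}" for g, n in by_group.items()))
    print(f"{len(cohort.traces)} traces of "
          f"{int(config.fs * config.move_window_s)} samples each")
    print(f"metadata/latents/trial parameters -> {out}")
    print(f"raw traces -> {scratch / 'traces.csv'}")


if __name__ == "__main__":
    main()
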