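#!/usr/bin/env python
"""Adjusted means (BLUEs), ANOVA mean squares, heritability, correlations.

Reads trial.csv; writes per-environment and combined BLUE tables, the
combined-ANOVA table, the trait summary (mean, range, SD, H2) and trait
correlation matrices.  Mixed-model REML at the full 236-line panel is the
slow step of the analysis; per-trait fits are printed as they finish.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import study_config

from mtgs.pipeline import stage_blues
from mtgs.synthetic_data import read_trial_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--profile", choices=["demo", "study-scale"], default="demo")
    args = ap.parse_args()

    cfg = study_config(args.seed, args.profile)
    out = Path(cfg.out_dir)
    trial = read_trial_csv(out / "trial.csv")
    stage_blues(cfg, trial, out)

    summary = pd.read_csv(out / "trait_summary.csv")
    h2 = summary.dropna(subset=["H2"]).set_index("trait")["H2"]
    print("broad-sense heritability (combined dataset):")
    for tr, v in h2.items():
        print(f"  {tr:>5}: {v:.2f}")
    anova = pd.read_csv(out / "anova_mean_squares.csv", index_col=0)
    sig = anova[anova["p_GxE"] < 0.05].index.tolist()
    print(f"traits with significant G x E at 5%: {sig}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
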