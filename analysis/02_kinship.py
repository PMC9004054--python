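#!/usr/bin/env python
"""Impute markers and build the additive genomic relationship matrix.

Reads markers.csv and trial.csv from the study results directory, writes
kinship.csv (checks excluded: they are design controls, not selection
candidates) and prints summary statistics of K.
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import study_config

from mtgs.kinship import MarkerMatrix
from mtgs.pipeline import stage_kinship
from mtgs.synthetic_data import read_trial_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--profile", choices=["demo", "study-scale"], default="demo")
    args = ap.parse_args()

    cfg = study_config(args.seed, args.profile)
    out = Path(cfg.out_dir)
    markers = MarkerMatrix.from_csv(out / "markers.csv")
    trial = read_trial_csv(out / "trial.csv")
    K = stage_kinship(cfg, markers, trial, out)

    diag = np.diag(K.values)
    off = K.values[~np.eye(K.n_lines, dtype=bool)]
    print(f"K: {K.n_lines} lines | mean diagonal {diag.mean():.3f} "
          f"| off-diagonal range [{off.min():.3f}, {off.max():.3f}]")
    print(f"min eigenvalue {np.linalg.eigvalsh(K.values)[0]:.2e} "
          f"(stabilized: {K.stabilized})")
    print(f"written to {out / 'kinship.csv'}")


if __name__ == "__main__":
    main()
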