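"""End-to-end orchestration: simulate -> kinship -> BLUEs -> CV comparison.

Every stage is a pure function of its inputs plus the :class:`RunConfig`;
stage outputs land as CSV/YAML files in the run directory, so a rerun with
an identical config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_validation import MaskSpec, make_splits, results_table, run_scheme
from .gs_models import GibbsConfig
from .kinship import KinshipMatrix, additive_relationship, impute_missing
from .phenotype_adjustment import (
    BlueTable,
    anova_mean_squares,
    blue_table,
    broad_sense_heritability,
    estimate_variance_components,
    trait_correlations,
)
from .synthetic_data import (
    DesignSpec,
    SimParams,
    simulate_markers,
    simulate_trial,
    write_trial_csv,
)

logger = logging.getLogger(__name__)

PRIMARY_TRAITS = ("HI", "GY", "GN", "SPI", "FE")
SECONDARY_TRAITS = ("CT", "NDVI")

PROFILES = {
    # scaled-down defaults for desk-scale runs; labelled in outputs
    "demo": {"n_markers": 2000, "burn_in": 500, "n_iter": 3000, "n_reps": 20},
    "study-scale": {"n_markers": 27466, "burn_in": 2000, "n_iter": 12000, "n_reps": 100},
}


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 1
    profile: str = "demo"
    design: DesignSpec = field(default_factory=DesignSpec)
    sim_params: SimParams = field(default_factory=SimParams)
    primary_traits: tuple[str, ...] = PRIMARY_TRAITS
    secondary_traits: tuple[str, ...] = SECONDARY_TRAITS
    cv_datasets: tuple[str, ...] = ("combined",)
    cv_primary_traits: tuple[str, ...] | None = None  # default: all primaries
    include_checks_in_gs: bool = False
    n_markers: int | None = None
    gibbs: GibbsConfig | None = None
    n_reps: int | None = None
    missing_rate: float = 0.01

    def resolved(self) -> dict:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        gibbs = self.gibbs or GibbsConfig(
            burn_in=prof["burn_in"], n_iter=prof["n_iter"], seed=self.seed
        )
        return {
            "n_markers": self.n_markers or prof["n_markers"],
            "gibbs": gibbs,
            "n_reps": self.n_reps or prof["n_reps"],
            "cv_traits": self.cv_primary_traits or self.primary_traits,
        }


def stage_simulate(cfg: RunConfig, out: Path):
    res = cfg.resolved()
    markers = simulate_markers(
        cfg.design.n_total, res["n_markers"], missing_rate=cfg.missing_rate, seed=cfg.seed
    )
    trial, truth = simulate_trial(markers, cfg.design, cfg.sim_params, seed=cfg.seed + 1)
    markers.to_csv(out / "markers.csv")
    write_trial_csv(trial, out / "trial.csv")
    truth.to_yaml(out / "simtruth.yaml")
    return markers, trial, truth


def stage_kinship(cfg: RunConfig, markers, trial, out: Path) -> KinshipMatrix:
    filled = impute_missing(markers, "mean")
    K = additive_relationship(filled)
    if not cfg.include_checks_in_gs:
        checks = list(dict.fromkeys(trial.loc[trial["is_check"], "entry_id"]))
        keep = [l for l in K.line_ids if l not in checks]
        K = K.subset(keep)
    K.to_csv(out / "kinship.csv")
    return K


def stage_blues(cfg: RunConfig, trial, out: Path):
    traits = list(cfg.primary_traits) + list(cfg.secondary_traits)
    datasets = list(cfg.design.environments) + ["combined"]
    blues: dict[str, BlueTable] = {}
    for ds in datasets:
        bt = blue_table(trial, ds, traits)
        bt.to_csv(out / f"blues_{ds}.csv")
        blues[ds] = bt

    anova = {}
    for tr in traits:
        tab = anova_mean_squares(trial, tr)
        anova[tr] = {
            "MS_G": tab.loc["Genotype (G)", "mean_sq"],
            "p_G": tab.loc["Genotype (G)", "p_value"],
            "MS_E": tab.loc["Environment (E)", "mean_sq"],
            "p_E": tab.loc["Environment (E)", "p_value"],
            "MS_GxE": tab.loc["G x E", "mean_sq"],
            "p_GxE": tab.loc["G x E", "p_value"],
        }
    pd.DataFrame(anova).T.to_csv(out / "anova_mean_squares.csv", index_label="trait")

    summary_rows = []
    for tr in traits:
        vc = estimate_variance_components(trial, tr)
        h2 = broad_sense_heritability(vc)
        for ds in datasets:
            col = blues[ds].values[tr].dropna()
            summary_rows.append(
                {
                    "trait": tr, "dataset": ds, "mean": col.mean(),
                    "min": col.min(), "max": col.max(), "sd": col.std(),
                    "H2": h2 if ds == "combined" else np.nan,
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "trait_summary.csv", index=False)

    for ds in datasets:
        r, p = trait_correlations(blues[ds])
        r.to_csv(out / f"correlations_{ds}.csv", index_label="trait")
        p.to_csv(out / f"correlation_pvalues_{ds}.csv", index_label="trait")
    return blues


def stage_cv(cfg: RunConfig, blues: dict[str, BlueTable], K: KinshipMatrix, out: Path):
    res = cfg.resolved()
    splits = make_splits(K.line_ids, cfg.design.train_fraction, res["n_reps"], cfg.seed)
    rows = []
    long_rows = []
    for ds in cfg.cv_datasets:
        bt = blues[ds]
        for trait in res["cv_traits"]:
            per_scheme = {}
            for scheme in ("ST-CV1", "MT-CV1", "MT-CV2"):
                mask = MaskSpec(scheme, trait, cfg.secondary_traits)
                per_scheme[scheme] = run_scheme(bt, K, mask, splits, res["gibbs"])
                for rep, r in enumerate(per_scheme[scheme].per_rep_r):
                    long_rows.append(
                        {"dataset": ds, "trait": trait, "scheme": scheme, "rep": rep, "r": r}
                    )
            rows.append(results_table(per_scheme))
            logger.info("CV %s/%s done", ds, trait)
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "profile", cfg.profile)
    table.to_csv(out / "predictive_ability.csv", index=False)
    pd.DataFrame(long_rows).to_csv(out / "predictive_ability_per_rep.csv", index=False)
    return table


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the run directory with all table CSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mtgs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        res = cfg.resolved()
        logger.info(
            "mtgs %s | profile=%s seed=%d | gibbs burn_in=%d n_iter=%d | cv reps=%d",
            __version__, cfg.profile, cfg.seed, res["gibbs"].burn_in,
            res["gibbs"].n_iter, res["n_reps"],
        )
        if cfg.profile != "study-scale":
            logger.info("scaled-down profile: chain lengths and replicate counts reduced")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"profile": cfg.profile, "seed": cfg.seed,
                            "design": dataclasses.asdict(cfg.design)}, fh)
        markers, trial, truth = stage_simulate(cfg, out)
        K = stage_kinship(cfg, markers, trial, out)
        blues = stage_blues(cfg, trial, out)
        stage_cv(cfg, blues, K, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
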