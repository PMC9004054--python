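"""Adjusted genotype means (BLUEs), ANOVA and broad-sense heritability.

Plot-level records from augmented trials are adjusted with mixed models:
genotype (test entries and checks as levels of one factor), environment and
the anthesis-date covariate enter as fixed effects; blocks and all
genotype-by-environment interactions are random.  Variance components come
from EM-REML (:mod:`mtgs.reml`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .reml import dummy_matrix, fit_mixed_model

COVARIATE = "days_to_anthesis"


@dataclass
class VarianceComponents:
    """Inputs of the broad-sense heritability formula."""

    sigma2_G: float
    sigma2_GxE: float
    sigma2_e: float
    n_env: int
    n_rep: int = 1


@dataclass
class BlueTable:
    """Adjusted genotype means for one dataset (an environment or 'combined')."""

    dataset_label: str
    values: pd.DataFrame  # genotype rows x trait columns, NaN allowed

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="genotype")

    @classmethod
    def from_csv(cls, path, dataset_label: str) -> "BlueTable":
        return cls(dataset_label, pd.read_csv(path, index_col=0))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _design_single_env(sub: pd.DataFrame, include_covariate: bool):
    Zg, levels = dummy_matrix(sub["entry_id"])
    names = [f"geno[{g}]" for g in levels]
    cols = [Zg]
    if include_covariate and COVARIATE in sub:
        cov = sub[COVARIATE].to_numpy(dtype=float)
        cols.append((cov - cov.mean())[:, None])
        names.append(COVARIATE)
    return np.hstack(cols), names, levels


def fit_blues_single_env(
    trial: pd.DataFrame, env: str, trait: str, include_covariate: bool = True
) -> pd.Series:
    """BLUEs for one trait in one environment.

    Genotype and the centred anthesis covariate are fixed; blocks are
    random.  The returned value per test entry is its adjusted mean at the
    covariate mean; checks are fitted but excluded from the output.
    """
    sub = trial[(trial["env"] == env) & trial[trait].notna()].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"environment {env!r} has no records for trait {trait!r}")
    X, names, levels = _design_single_env(sub, include_covariate)
    _check_full_rank(X, names)
    Zb, _ = dummy_matrix(sub["block"])
    fit = fit_mixed_model(sub[trait].to_numpy(dtype=float), X, {"block": Zb})
    vals = pd.Series(fit.beta[: len(levels)], index=levels, name=trait)
    checks = set(sub.loc[sub["is_check"], "entry_id"])
    return vals[[g for g in vals.index if g not in checks]]


def fit_blues_combined(
    trial: pd.DataFrame, trait: str, include_covariate: bool = True
) -> pd.Series:
    """BLUEs across environments.

    Genotype, environment and the covariate are fixed; genotype-by-
    environment and block-within-environment are random.  Returns each test
    entry's adjusted mean averaged over the fitted environment effects.
    """
    envs = list(dict.fromkeys(trial["env"]))
    if len(envs) < 2:
        raise ValueError("combined analysis needs at least 2 environments")
    sub = trial[trial[trait].notna()].reset_index(drop=True)
    Zg, levels = dummy_matrix(sub["entry_id"])
    names = [f"geno[{g}]" for g in levels]
    env_arr = sub["env"].to_numpy()
    env_cols = [(env_arr == e).astype(float)[:, None] for e in envs[1:]]
    names += [f"env[{e}]" for e in envs[1:]]
    cols = [Zg, *env_cols]
    if include_covariate and COVARIATE in sub:
        cov = sub[COVARIATE].to_numpy(dtype=float)
        cols.append((cov - cov.mean())[:, None])
        names.append(COVARIATE)
    X = np.hstack(cols)
    _check_full_rank(X, names)
    gxe = sub["entry_id"].astype(str) + "|" + sub["env"].astype(str)
    blk = sub["env"].astype(str) + "|" + sub["block"].astype(str)
    Zgxe, _ = dummy_matrix(gxe)
    Zblk, _ = dummy_matrix(blk)
    fit = fit_mixed_model(
        sub[trait].to_numpy(dtype=float), X, {"gxe": Zgxe, "block_in_env": Zblk}
    )
    env_eff = np.concatenate([[0.0], fit.beta[len(levels): len(levels) + len(envs) - 1]])
    vals = pd.Series(fit.beta[: len(levels)] + env_eff.mean(), index=levels, name=trait)
    checks = set(sub.loc[sub["is_check"], "entry_id"])
    return vals[[g for g in vals.index if g not in checks]]


def blue_table(trial: pd.DataFrame, dataset: str, traits: list[str] | None = None,
               include_covariate: bool = True) -> BlueTable:
    """All-trait BLUE table for one environment or the combined dataset."""
    traits = traits or [c for c in trial.columns
                        if c not in ("env", "block", "entry_id", "is_check", "check_id", COVARIATE)]
    entries = list(dict.fromkeys(trial.loc[~trial["is_check"], "entry_id"]))
    cols = {}
    for tr in traits:
        if dataset == "combined":
            cols[tr] = fit_blues_combined(trial, tr, include_covariate)
        else:
            cols[tr] = fit_blues_single_env(trial, dataset, tr, include_covariate)
    values = pd.DataFrame(cols).reindex(entries)
    return BlueTable(dataset, values)


def anova_mean_squares(trial: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Combined-ANOVA mean squares for genotype, environment and G x E.

    Sequential (Type I) sums of squares from the fixed two-way model with
    interaction; the residual comes from replicated plots (the checks, in an
    augmented design).  Requires at least two environments.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    envs = trial["env"].unique()
    if len(envs) < 2:
        raise ValueError("interaction undefined with a single environment")
    sub = trial[trial[trait].notna()].rename(columns={trait: "_y"})
    model = ols("_y ~ C(entry_id) + C(env) + C(entry_id):C(env)", data=sub).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    rows = {
        "Genotype (G)": "C(entry_id)",
        "Environment (E)": "C(env)",
        "G x E": "C(entry_id):C(env)",
        "Residual": "Residual",
    }
    out = pd.DataFrame(
        {
            "df": [tab.loc[v, "df"] for v in rows.values()],
            "mean_sq": [tab.loc[v, "sum_sq"] / tab.loc[v, "df"] for v in rows.values()],
            "F": [tab.loc[v, "F"] for v in rows.values()],
            "p_value": [tab.loc[v, "PR(>F)"] for v in rows.values()],
        },
        index=list(rows),
    )
    return out


def estimate_variance_components(trial: pd.DataFrame, trait: str,
                                 include_covariate: bool = True) -> VarianceComponents:
    """REML variance components with genotype, env, G x E and blocks random.

    Feeds the broad-sense heritability formula; only the intercept and the
    covariate stay fixed, matching the all-random heritability model.
    """
    sub = trial[trial[trait].notna()].reset_index(drop=True)
    envs = list(dict.fromkeys(sub["env"]))
    cols = [np.ones((len(sub), 1))]
    if include_covariate and COVARIATE in sub:
        cov = sub[COVARIATE].to_numpy(dtype=float)
        cols.append((cov - cov.mean())[:, None])
    X = np.hstack(cols)
    Zg, _ = dummy_matrix(sub["entry_id"])
    Ze, _ = dummy_matrix(sub["env"])
    Zgxe, _ = dummy_matrix(sub["entry_id"].astype(str) + "|" + sub["env"].astype(str))
    Zblk, _ = dummy_matrix(sub["env"].astype(str) + "|" + sub["block"].astype(str))
    fit = fit_mixed_model(
        sub[trait].to_numpy(dtype=float), X,
        {"genotype": Zg, "env": Ze, "gxe": Zgxe, "block": Zblk},
    )
    entries = sub[~sub["is_check"]]
    n_rep = int(round(entries.groupby(["env", "entry_id"]).size().median())) if len(entries) else 1
    return VarianceComponents(
        sigma2_G=fit.sigma2["genotype"],
        sigma2_GxE=fit.sigma2["gxe"],
        sigma2_e=fit.sigma2["residual"],
        n_env=len(envs),
        n_rep=max(n_rep, 1),
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H2 = s2G / (s2G + s2GxE / n + s2e / (n r)).

    n is the number of environments, r the replications per environment
    (r = 1 for an augmented design).
    """
    if vc.n_env < 1 or vc.n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    if min(vc.sigma2_G, vc.sigma2_GxE, vc.sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    denom = vc.sigma2_G + vc.sigma2_GxE / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return vc.sigma2_G / denom


def trait_correlations(blues: BlueTable | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among traits with two-sided p.

    Constant columns yield NaN for their pairs; pairs need >= 3 complete
    genotype rows.
    """
    df = blues.values if isinstance(blues, BlueTable) else blues
    traits = list(df.columns)
    t = len(traits)
    r = np.full((t, t), np.nan)
    p = np.full((t, t), np.nan)
    for i in range(t):
        for j in range(i, t):
            pair = df[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )
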