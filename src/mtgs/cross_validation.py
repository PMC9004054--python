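"""Monte-Carlo cross-validation schemes for genomic prediction.

ST-CV1: single-trait model; test lines contribute genotypes only.
MT-CV1: multi-trait model; test lines have every trait masked.
MT-CV2: multi-trait model; test lines keep their secondary-trait phenotypes
and only the primary trait is masked.

Predictive ability is the mean Pearson correlation between held-out
observed primary-trait values and model predictions over the replicates,
with identical random train/test splits shared across schemes so the
comparison is paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gs_models import (
    GibbsConfig,
    MtModelInput,
    StModelInput,
    fit_multi_trait,
    fit_single_trait,
)
from .kinship import KinshipMatrix
from .phenotype_adjustment import BlueTable

logger = logging.getLogger(__name__)

SCHEMES = ("ST-CV1", "MT-CV1", "MT-CV2")


@dataclass
class CvSplit:
    rep_index: int
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class MaskSpec:
    scheme: str
    primary_trait: str
    secondary_traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.scheme.startswith("MT") and not self.secondary_traits:
            raise ValueError("multi-trait schemes need at least one secondary trait")


@dataclass
class CvResult:
    scheme: str
    trait: str
    dataset_label: str
    per_rep_r: np.ndarray
    n_valid_reps: int
    predictions: list[pd.Series] = field(default_factory=list, repr=False)

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.per_rep_r)) if self.n_valid_reps else float("nan")

    @property
    def se_r(self) -> float:
        valid = self.per_rep_r[~np.isnan(self.per_rep_r)]
        return float(np.std(valid, ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else float("nan")


def make_splits(
    genotype_ids,
    train_fraction: float = 0.7,
    n_reps: int = 100,
    seed: int = 0,
) -> list[CvSplit]:
    """Independent uniform random train/test partitions of the panel.

    Train size is floor(train_fraction * n) in every replicate; for the
    236-line panel at 0.7 this gives 165 training and 71 test lines.
    """
    ids = list(genotype_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 genotypes to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(n_reps):
        perm = rng.permutation(n)
        train = sorted(ids[i] for i in perm[:n_train])
        test = sorted(ids[i] for i in perm[n_train:])
        splits.append(CvSplit(rep, train, test))
    return splits


def _rep_config(config: GibbsConfig, rep_index: int) -> GibbsConfig:
    # independent chains per replicate, deterministic in (global seed, rep)
    seed = int(np.random.SeedSequence(entropy=config.seed, spawn_key=(rep_index,))
               .generate_state(1)[0] % (2**31))
    return GibbsConfig(
        burn_in=config.burn_in, n_iter=config.n_iter, thin=config.thin, seed=seed,
        prior_df_variance=config.prior_df_variance,
        prior_df_wishart_extra=config.prior_df_wishart_extra,
        fixed_sigma2_g=config.fixed_sigma2_g, fixed_sigma2_e=config.fixed_sigma2_e,
        fixed_Sigma=config.fixed_Sigma, fixed_R=config.fixed_R,
    )


def run_scheme(
    blues: BlueTable | pd.DataFrame,
    K: KinshipMatrix,
    mask: MaskSpec,
    splits: list[CvSplit],
    config: GibbsConfig | None = None,
    keep_predictions: bool = False,
) -> CvResult:
    """Run one cross-validation scheme over the given splits.

    Held-out primary phenotypes are removed from the data the model sees
    (never merely down-weighted), so the masking can be audited by
    corrupting them and observing unchanged predictions.
    """
    config = config or GibbsConfig()
    df = blues.values if isinstance(blues, BlueTable) else blues
    label = blues.dataset_label if isinstance(blues, BlueTable) else "data"
    if mask.primary_trait not in df.columns:
        raise ValueError(f"primary trait {mask.primary_trait!r} not in BLUE table")
    missing_sec = [s for s in mask.secondary_traits if s not in df.columns]
    if missing_sec:
        raise ValueError(f"secondary traits not in BLUE table: {missing_sec}")
    df = df.reindex(K.line_ids)

    rs = np.full(len(splits), np.nan)
    preds_kept: list[pd.Series] = []
    for pos, split in enumerate(splits):
        cfg = _rep_config(config, split.rep_index)
        test = split.test_ids
        if mask.scheme == "ST-CV1":
            y = df[mask.primary_trait].copy()
            y[y.index.isin(test)] = np.nan
            summary = fit_single_trait(StModelInput(y, K), cfg)
        else:
            Y = df[[mask.primary_trait, *mask.secondary_traits]].copy()
            Y.loc[Y.index.isin(test), mask.primary_trait] = np.nan
            if mask.scheme == "MT-CV1":
                Y.loc[Y.index.isin(test), list(mask.secondary_traits)] = np.nan
            summary = fit_multi_trait(
                MtModelInput(Y, K, mask.primary_trait, mask.secondary_traits), cfg
            )
        pred = summary.mu_hat[summary.trait_names.index(mask.primary_trait)] \
            + summary.gebv[mask.primary_trait].loc[test]
        if keep_predictions:
            preds_kept.append(pred.rename(f"rep{split.rep_index}"))
        obs = df[mask.primary_trait].loc[test]
        ok = obs.notna()
        if ok.sum() < 3 or np.std(obs[ok]) == 0 or np.std(pred[ok]) == 0:
            logger.warning("rep %d invalid (degenerate observed/predicted values)", split.rep_index)
            continue
        rs[pos] = stats.pearsonr(obs[ok], pred[ok]).statistic
    return CvResult(
        scheme=mask.scheme,
        trait=mask.primary_trait,
        dataset_label=label,
        per_rep_r=rs,
        n_valid_reps=int(np.sum(~np.isnan(rs))),
        predictions=preds_kept,
    )


def percent_increase(st: CvResult, mt: CvResult) -> float:
    """Percent change in predictive ability from the ST to the MT scheme."""
    if st.trait != mt.trait or st.dataset_label != mt.dataset_label:
        raise ValueError("results compare different traits or datasets")
    if not np.isfinite(st.mean_r) or st.mean_r <= 0:
        logger.warning("percent increase undefined: ST mean_r = %s", st.mean_r)
        return float("nan")
    return 100.0 * (mt.mean_r - st.mean_r) / st.mean_r


def paired_comparison(a: CvResult, b: CvResult) -> tuple[float, float]:
    """One-sided paired t-test that b's per-rep r exceeds a's.

    Returns (mean difference b - a, one-sided p-value), using only
    replicates valid in both results.
    """
    ok = ~np.isnan(a.per_rep_r) & ~np.isnan(b.per_rep_r)
    diff = b.per_rep_r[ok] - a.per_rep_r[ok]
    if diff.size < 2:
        return float("nan"), float("nan")
    res = stats.ttest_rel(b.per_rep_r[ok], a.per_rep_r[ok], alternative="greater")
    return float(diff.mean()), float(res.pvalue)


def results_table(results: dict[str, CvResult]) -> pd.DataFrame:
    """One row per (dataset, trait): scheme means and % increase ST->MT-CV2."""
    st, mt1, mt2 = results["ST-CV1"], results.get("MT-CV1"), results.get("MT-CV2")
    row = {
        "dataset": st.dataset_label,
        "trait": st.trait,
        "ST-CV1": st.mean_r,
        "ST-CV1_se": st.se_r,
    }
    if mt1 is not None:
        row["MT-CV1"] = mt1.mean_r
        row["MT-CV1_se"] = mt1.se_r
    if mt2 is not None:
        row["MT-CV2"] = mt2.mean_r
        row["MT-CV2_se"] = mt2.se_r
        row["pct_increase"] = percent_increase(st, mt2)
    return pd.DataFrame([row])
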