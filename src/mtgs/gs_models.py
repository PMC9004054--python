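"""Bayesian genomic prediction: single-trait and multi-trait Gibbs samplers.

Single-trait model:  y = mu + Z a + e with a ~ N(0, K s2g), e ~ N(0, I s2e).
Multi-trait model: stacked per-trait equations with a ~ MVN(0, Sigma (x) K)
and e ~ MVN(0, R (x) I); Sigma is an unstructured t x t genetic covariance
and R a diagonal residual matrix.

Both samplers work in the eigenbasis of K (K = U D U'), where the genetic-
value full conditionals factor per eigen-coordinate: a scalar update in the
single-trait case and a t x t solve in the multi-trait case.  Missing
phenotypes are handled by data augmentation, so genomic estimated breeding
values (GEBVs) and predictions are produced for unphenotyped genotypes.

Priors (weakly informative defaults, all exposed in :class:`GibbsConfig`):
scaled-inverse-chi2 with 5 df for every scalar variance, scale set so the
prior mode equals half the observed sample variance; inverse-Wishart with
t + 3 df and scale 0.5 * diag(sample variances) for Sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KinshipMatrix

import logging

logger = logging.getLogger(__name__)

EIG_TOL = 1e-8


@dataclass
class GibbsConfig:
    burn_in: int = 2000
    n_iter: int = 12000
    thin: int = 1
    seed: int = 0
    prior_df_variance: float = 5.0
    prior_df_wishart_extra: float = 3.0  # Wishart df = n_traits + this
    # test hooks: fix variance parameters instead of sampling them
    fixed_sigma2_g: float | None = None
    fixed_sigma2_e: float | None = None
    fixed_Sigma: np.ndarray | None = None
    fixed_R: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if min(self.burn_in, self.thin) < 0 or self.n_iter <= 0 or self.thin < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class StModelInput:
    """One trait's adjusted means aligned to a kinship matrix."""

    y: pd.Series  # indexed by genotype; NaN = missing
    K: KinshipMatrix

    def __post_init__(self) -> None:
        if list(self.y.index) != list(self.K.line_ids):
            raise ValueError("y and K must share genotype order")


@dataclass
class MtModelInput:
    """Genotype x trait matrix of adjusted means with arbitrary missingness."""

    Y: pd.DataFrame
    K: KinshipMatrix
    primary_trait: str | None = None
    secondary_traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.Y.index) != list(self.K.line_ids):
            raise ValueError("Y and K must share genotype order")
        n_obs = self.Y.notna().sum(axis=0)
        if (n_obs < 2).any():
            bad = list(n_obs.index[n_obs < 2])
            raise ValueError(f"traits with fewer than 2 observations: {bad}")


@dataclass
class PosteriorSummary:
    """Posterior means and retained chains from one Gibbs run."""

    line_ids: list[str]
    trait_names: list[str]
    mu_hat: np.ndarray  # (t,)
    gebv: pd.DataFrame  # n x t posterior-mean genetic values
    y_pred: pd.DataFrame  # n x t, posterior-mean mu + g at missing cells, NaN elsewhere
    sigma2_g: np.ndarray  # (t,) posterior-mean genetic variances (Sigma diagonal)
    sigma2_e: np.ndarray  # (t,) posterior-mean residual variances (R diagonal)
    Sigma_hat: np.ndarray  # t x t
    R_hat: np.ndarray  # t x t diagonal
    chains: dict[str, np.ndarray] = field(default_factory=dict)

    def fitted(self) -> pd.DataFrame:
        """mu + GEBV for every genotype and trait."""
        return self.gebv + self.mu_hat


def eig_psd(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a PSD kinship; small negatives are clipped."""
    lam, U = np.linalg.eigh(K.values)
    if lam[0] < -EIG_TOL * max(1.0, lam[-1]):
        raise ValueError(
            f"kinship is not PSD (min eigenvalue {lam[0]:.3g}); "
            "apply mtgs.kinship.stabilize_psd first"
        )
    return U, np.clip(lam, 0.0, None)


def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    return scale_sum / rng.chisquare(df)


def _prior_scale(df: float, sample_var: float) -> float:
    # mode of scaled-inv-chi2(df, s2) is df*s2/(df+2); target half the variance
    return 0.5 * sample_var * (df + 2.0) / df


class _BatchAccumulator:
    """Batch means of a vector chain, for Monte-Carlo standard errors."""

    def __init__(self, n_kept: int, dim: int, n_batches: int = 50):
        self.batch = max(1, n_kept // n_batches)
        self.sums = np.zeros(dim)
        self.count = 0
        self.means: list[np.ndarray] = []

    def add(self, x: np.ndarray) -> None:
        self.sums += x
        self.count += 1
        if self.count == self.batch:
            self.means.append(self.sums / self.count)
            self.sums = np.zeros_like(self.sums)
            self.count = 0

    def result(self) -> np.ndarray:
        return np.array(self.means) if self.means else np.empty((0, self.sums.size))


def fit_single_trait(inp: StModelInput, config: GibbsConfig | None = None) -> PosteriorSummary:
    """Gibbs sampler for the single-trait genomic model.

    Cycles (g | rest) in the eigenbasis of K, (mu | rest), the two variances
    from scaled-inverse-chi2 full conditionals, and data augmentation for
    missing phenotypes.  Deterministic under a fixed config seed.
    """
    config = config or GibbsConfig()
    y = inp.y.to_numpy(dtype=float)
    n = y.size
    obs = ~np.isnan(y)
    if obs.sum() < 10:
        raise ValueError("need at least 10 observed phenotypes")
    U, d = eig_psd(inp.K)
    pos = d > EIG_TOL
    rng = np.random.default_rng(config.seed)

    var_y = float(np.var(y[obs])) or 1.0
    df0 = config.prior_df_variance
    s0g = _prior_scale(df0, var_y)
    s0e = _prior_scale(df0, var_y)
    logger.debug("ST priors: df=%g scale_g=%.4g scale_e=%.4g", df0, s0g, s0e)

    mu = float(np.mean(y[obs]))
    s2g = config.fixed_sigma2_g if config.fixed_sigma2_g is not None else 0.5 * var_y
    s2e = config.fixed_sigma2_e if config.fixed_sigma2_e is not None else 0.5 * var_y
    g = np.zeros(n)
    yaug = np.where(obs, y, mu)

    kept = config.n_iter - config.burn_in
    sum_g = np.zeros(n)
    sum_mu = 0.0
    sum_s2g = 0.0
    sum_s2e = 0.0
    batches = _BatchAccumulator(kept // config.thin if config.thin > 1 else kept, n)
    chain_rows = []

    for it in range(config.n_iter):
        # genetic values in the eigenbasis: diagonal posterior
        ytil = U.T @ (yaug - mu)
        gt = np.zeros(n)
        prec = 1.0 / s2e + 1.0 / (d[pos] * s2g)
        var_i = 1.0 / prec
        mean_i = var_i * ytil[pos] / s2e
        gt[pos] = mean_i + np.sqrt(var_i) * rng.standard_normal(pos.sum())
        g = U @ gt

        mu = float(rng.normal(np.mean(yaug - g), np.sqrt(s2e / n)))

        if config.fixed_sigma2_g is None:
            ss_g = float(np.sum(gt[pos] ** 2 / d[pos]))
            s2g = _scaled_inv_chi2(rng, df0 + pos.sum(), df0 * s0g + ss_g)
        if config.fixed_sigma2_e is None:
            resid = yaug - mu - g
            s2e = _scaled_inv_chi2(rng, df0 + n, df0 * s0e + float(resid @ resid))

        miss = ~obs
        if miss.any():
            yaug[miss] = mu + g[miss] + rng.standard_normal(miss.sum()) * np.sqrt(s2e)

        if it >= config.burn_in:
            sum_g += g
            sum_mu += mu
            sum_s2g += s2g
            sum_s2e += s2e
            batches.add(g)
            if (it - config.burn_in) % config.thin == 0:
                chain_rows.append((mu, s2g, s2e))

    gbar = sum_g / kept
    mubar = sum_mu / kept
    trait = inp.y.name or "trait"
    gebv = pd.DataFrame({trait: gbar}, index=inp.K.line_ids)
    y_pred = pd.DataFrame({trait: np.where(obs, np.nan, mubar + gbar)}, index=inp.K.line_ids)
    chains = np.array(chain_rows)
    return PosteriorSummary(
        line_ids=list(inp.K.line_ids),
        trait_names=[trait],
        mu_hat=np.array([mubar]),
        gebv=gebv,
        y_pred=y_pred,
        sigma2_g=np.array([sum_s2g / kept]),
        sigma2_e=np.array([sum_s2e / kept]),
        Sigma_hat=np.array([[sum_s2g / kept]]),
        R_hat=np.array([[sum_s2e / kept]]),
        chains={
            "mu": chains[:, 0],
            "sigma2_g": chains[:, 1],
            "sigma2_e": chains[:, 2],
            "gebv_batch_means": batches.result(),
        },
    )


def _draw_inv_wishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw with a jitter-and-retry guard for PD failures."""
    jitter = 0.0
    base = float(np.mean(np.diag(scale)))
    for _ in range(5):
        try:
            draw = np.atleast_2d(
                stats.invwishart.rvs(df=df, scale=scale + jitter * np.eye(scale.shape[0]),
                                     random_state=rng)
            )
            np.linalg.cholesky(draw)
            return draw
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-8 * base)
    raise np.linalg.LinAlgError("inverse-Wishart draw remained non-PD after jitter retries")


def fit_multi_trait(inp: MtModelInput, config: GibbsConfig | None = None) -> PosteriorSummary:
    """Gibbs sampler for the multi-trait genomic model.

    Per iteration: each eigen-coordinate's t-vector of genetic values is a
    t x t Gaussian solve (batched across coordinates); Sigma is drawn from
    its inverse-Wishart full conditional, the diagonal of R from scaled-
    inverse-chi2 conditionals, intercepts from their Gaussian conditionals,
    and every missing phenotype cell from its conditional normal.
    """
    config = config or GibbsConfig()
    Y = inp.Y.to_numpy(dtype=float)
    n, t = Y.shape
    obs = ~np.isnan(Y)
    U, d = eig_psd(inp.K)
    pos = d > EIG_TOL
    npos = int(pos.sum())
    dpos = d[pos]
    rng = np.random.default_rng(config.seed)

    col_var = np.nanvar(Y, axis=0)
    col_var[col_var <= 0] = 1.0
    df0 = config.prior_df_variance
    s0_r = _prior_scale(df0, col_var)  # per-trait residual prior scales
    nu0 = t + config.prior_df_wishart_extra
    # scale set so the prior MEAN (psi / (nu - t - 1)) is half the sample
    # variance per trait, the multivariate analogue of the scalar priors
    psi0 = 0.5 * np.diag(col_var) * (nu0 - t - 1.0)
    logger.debug("MT priors: df_resid=%g wishart_df=%g psi0_diag=%s",
                 df0, nu0, np.diag(psi0))

    mu = np.nanmean(Y, axis=0)
    Sigma = config.fixed_Sigma.copy() if config.fixed_Sigma is not None else 0.5 * np.diag(col_var)
    R = (np.diag(config.fixed_R).astype(float).copy()
         if config.fixed_R is not None else 0.5 * col_var)
    Gt = np.zeros((n, t))  # genetic values in the eigenbasis
    Yaug = np.where(obs, Y, mu)

    kept = config.n_iter - config.burn_in
    sum_Gt = np.zeros((n, t))
    sum_mu = np.zeros(t)
    sum_Sigma = np.zeros((t, t))
    sum_R = np.zeros(t)
    chain_mu, chain_Sigma, chain_R = [], [], []

    eye_rows = np.arange(t)
    for it in range(config.n_iter):
        # --- genetic values: batched t x t solves per eigen-coordinate
        Sinv = np.linalg.inv(Sigma)
        Rinv = 1.0 / R
        Ytil = U.T @ (Yaug - mu)
        A = np.zeros((npos, t, t))
        A[:] = Sinv[None, :, :] / dpos[:, None, None]
        A[:, eye_rows, eye_rows] += Rinv[None, :]
        cov = np.linalg.inv(A)
        cov = (cov + np.swapaxes(cov, 1, 2)) / 2.0
        b = Ytil[pos] * Rinv[None, :]
        mean = np.einsum("ijk,ik->ij", cov, b)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(t)[None, :, :])
        z = rng.standard_normal((npos, t))
        Gt = np.zeros((n, t))
        Gt[pos] = mean + np.einsum("ijk,ik->ij", L, z)
        G = U @ Gt

        # --- intercepts
        resid_mean = (Yaug - G).mean(axis=0)
        mu = resid_mean + rng.standard_normal(t) * np.sqrt(R / n)

        # --- genetic covariance
        if config.fixed_Sigma is None:
            S = (Gt[pos].T / dpos) @ Gt[pos]
            Sigma = _draw_inv_wishart(rng, nu0 + npos, psi0 + S)

        # --- residual variances (R diagonal)
        if config.fixed_R is None:
            E = Yaug - mu - G
            ss = np.einsum("ij,ij->j", E, E)
            R = (df0 * s0_r + ss) / rng.chisquare(df0 + n, size=t)

        # --- data augmentation for missing cells
        miss = ~obs
        if miss.any():
            noise = rng.standard_normal(Y.shape) * np.sqrt(R)
            Yaug = np.where(obs, Y, mu + G + noise)

        if it >= config.burn_in:
            sum_Gt += Gt
            sum_mu += mu
            sum_Sigma += Sigma
            sum_R += R
            if (it - config.burn_in) % config.thin == 0:
                chain_mu.append(mu.copy())
                chain_Sigma.append(Sigma.copy())
                chain_R.append(R.copy())

    Gbar = U @ (sum_Gt / kept)
    mubar = sum_mu / kept
    Sigma_bar = sum_Sigma / kept
    R_bar = sum_R / kept
    traits = list(inp.Y.columns)
    gebv = pd.DataFrame(Gbar, index=inp.K.line_ids, columns=traits)
    pred = mubar + Gbar
    y_pred = pd.DataFrame(np.where(obs, np.nan, pred), index=inp.K.line_ids, columns=traits)
    return PosteriorSummary(
        line_ids=list(inp.K.line_ids),
        trait_names=traits,
        mu_hat=mubar,
        gebv=gebv,
        y_pred=y_pred,
        sigma2_g=np.diag(Sigma_bar).copy(),
        sigma2_e=R_bar.copy(),
        Sigma_hat=Sigma_bar,
        R_hat=np.diag(R_bar),
        chains={
            "mu": np.array(chain_mu),
            "Sigma": np.array(chain_Sigma),
            "R": np.array(chain_R),
        },
    )


def predict(summary: PosteriorSummary, genotype_ids, trait: str) -> pd.Series:
    """Posterior-mean predictions (intercept + GEBV) for requested genotypes.

    Equals the posterior-mean imputation for genotypes whose phenotype was
    missing during the fit, and the fitted value for observed ones.
    """
    if trait not in summary.trait_names:
        raise KeyError(f"trait {trait!r} was not in the fit")
    unknown = [g for g in genotype_ids if g not in summary.gebv.index]
    if unknown:
        raise KeyError(f"unknown genotype ids: {unknown}")
    j = summary.trait_names.index(trait)
    vals = summary.mu_hat[j] + summary.gebv[trait].loc[list(genotype_ids)]
    return vals.rename(trait)
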