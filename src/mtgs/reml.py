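"""EM-REML for Gaussian mixed models with independent variance components.

Model: y = X b + sum_k Z_k u_k + e, with u_k ~ N(0, sigma2_k I) and
e ~ N(0, sigma2_e I).  Estimation iterates the EM-REML updates on the
V-matrix form until the restricted log-likelihood changes by less than a
tolerance; negative estimates are floored during iteration and truncated to
zero on exit.  Suited to the moderate problem sizes of single-site trials
(hundreds to ~1000 plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

_FLOOR = 1e-10


@dataclass
class MixedModelFit:
    beta: np.ndarray
    sigma2: dict[str, float]  # per random term, plus "residual"
    random_effects: dict[str, np.ndarray]  # BLUPs
    loglik: float
    converged: bool
    n_iter: int
    fixed_cov: np.ndarray  # Cov(beta_hat)


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: dict[str, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixedModelFit:
    """Estimate variance components by EM-REML and return GLS fixed effects.

    ``random_terms`` maps a term name to its incidence matrix Z_k.  The
    fixed-effect design X must be full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    names = list(random_terms)
    ZZt = {k: random_terms[k] @ random_terms[k].T for k in names}
    vary = float(np.var(y)) or 1.0
    sig = {k: vary / (len(names) + 1) for k in names}
    sig_e = vary / (len(names) + 1)

    def build(sig, sig_e):
        V = sig_e * np.eye(n)
        for k in names:
            V += sig[k] * ZZt[k]
        cho = linalg.cho_factor(V, lower=True)
        Vinv = linalg.cho_solve(cho, np.eye(n))
        XtVinv = X.T @ Vinv
        XtVinvX = XtVinv @ X
        cfix = linalg.cho_factor(XtVinvX)
        P = Vinv - XtVinv.T @ linalg.cho_solve(cfix, XtVinv)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
        logdet_X = 2.0 * np.sum(np.log(np.diag(cfix[0])))
        Py = P @ y
        ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
        return Vinv, XtVinvX, P, Py, ll

    Vinv, XtVinvX, P, Py, ll = build(sig, sig_e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for k in names:
            PZk = P @ ZZt[k]
            grad = float(Py @ ZZt[k] @ Py) - float(np.trace(PZk))
            sig[k] = max(sig[k] + (sig[k] ** 2 / ZZt[k].shape[0]) * grad, _FLOOR)
        grad_e = float(Py @ Py) - float(np.trace(P))
        sig_e = max(sig_e + (sig_e**2 / n) * grad_e, _FLOOR)
        Vinv, XtVinvX, P, Py, ll_new = build(sig, sig_e)
        dll = abs(ll_new - ll)
        ll = ll_new
        if dll < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM-REML did not converge in %d iterations (last dll=%.2g)", it, dll)

    XtVy = X.T @ Vinv @ y
    beta = np.linalg.solve(XtVinvX, XtVy)
    fixed_cov = np.linalg.inv(XtVinvX)
    resid_proj = Py  # P y = Vinv (y - X beta)
    blups = {k: sig[k] * (random_terms[k].T @ resid_proj) for k in names}
    sigma2 = {k: (0.0 if sig[k] <= 2 * _FLOOR else float(sig[k])) for k in names}
    sigma2["residual"] = float(sig_e)
    return MixedModelFit(beta, sigma2, blups, float(ll), converged, it, fixed_cov)


def dummy_matrix(labels) -> tuple[np.ndarray, list]:
    """Full-rank one-hot incidence matrix for a factor (all levels)."""
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels.tolist()))
    Z = (labels[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels
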