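"""Simple MCMC chain diagnostics: ESS, Monte-Carlo SE, Geweke z."""

from __future__ import annotations

import numpy as np


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(chain, dtype=float)
    m = x.size
    if m < 4 or np.var(x) == 0:
        return float(m)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1:] / (np.arange(m, 0, -1) * np.var(x))
    # sum consecutive pairs until the pair sum goes negative (Geyer)
    s = 0.0
    for k in range(1, m // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < m else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    ess = m / (1.0 + 2.0 * s)
    return float(np.clip(ess, 1.0, m))


def mcse(chain: np.ndarray) -> float:
    """Monte-Carlo standard error of the chain mean."""
    x = np.asarray(chain, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(effective_sample_size(x)))


def mcse_from_batch_means(batch_means: np.ndarray) -> np.ndarray:
    """Per-coordinate MC SE of the posterior mean from stored batch means."""
    bm = np.asarray(batch_means, dtype=float)
    nb = bm.shape[0]
    if nb < 2:
        return np.full(bm.shape[1] if bm.ndim > 1 else 1, np.inf)
    return np.std(bm, axis=0, ddof=1) / np.sqrt(nb)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    x = np.asarray(chain, dtype=float)
    m = x.size
    a = x[: max(int(first * m), 2)]
    b = x[-max(int(last * m), 2):]
    se2 = mcse(a) ** 2 + mcse(b) ** 2
    if se2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(se2))
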