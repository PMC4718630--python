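"""MCMC convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_samples). Computes sqrt(V_hat / W) with
    V_hat = (n-1)/n * W + B/n, where W is the mean within-chain variance
    and B the between-chain variance of chain means (both with ddof=1).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    w = np.mean(np.var(chains, axis=1, ddof=1))
    b = n * np.var(np.mean(chains, axis=1), ddof=1)
    if w == 0:
        return 1.0
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def hpd(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted samples."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if level == 1:
        return float(x[0]), float(x[-1])
    k = int(np.ceil(level * n))
    k = min(max(k, 2), n)
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def half_sample_mode(samples: np.ndarray) -> float:
    """Robust parameter-free mode estimate by recursive half-sample
    narrowing (Bickel & Fruehwirth's HSM)."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    while x.size > 3:
        k = (x.size + 1) // 2
        widths = x[k - 1:] - x[:x.size - k + 1]
        i = int(np.argmin(widths))
        x = x[i:i + k]
    if x.size == 3:
        # pick the denser pair
        return float((x[0] + x[1]) / 2 if x[1] - x[0] <= x[2] - x[1]
                     else (x[1] + x[2]) / 2)
    return float(np.mean(x))


def mcse(samples: np.ndarray, batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean by batch means (accounts
    for autocorrelation within a chain)."""
    x = np.asarray(samples, dtype=float).ravel()
    nb = min(batches, x.size // 2)
    if nb < 2:
        return float(np.std(x, ddof=1) / np.sqrt(x.size))
    bs = x.size // nb
    means = x[:nb * bs].reshape(nb, bs).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))
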