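"""Convergence diagnostics for multi-chain MCMC output."""

from __future__ import annotations

import numpy as np

__all__ = ["rhat"]


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each of the ``m`` chains (rows) is split in half, giving ``2m``
    sequences of length ``n/2``; R-hat compares the between-sequence
    variance of the means with the pooled within-sequence variance.  Values
    near 1 indicate the chains are sampling the same distribution; the
    conventional alarm level is 1.1.

    Parameters
    ----------
    chains
        (m, n) array of draws, one row per chain, equal lengths, m >= 2.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    n = chains.shape[1]
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    means = split.mean(axis=1)
    within = split.var(axis=1, ddof=1)
    W = within.mean()
    B_over_n = np.var(means, ddof=1)  # = B / n_split
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (half - 1) / half * W + B_over_n
    return float(np.sqrt(var_plus / W))
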