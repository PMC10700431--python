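"""Autocorrelation utilities shared by the sampler diagnostics and the
bridge-sampling error estimate."""

from __future__ import annotations

import numpy as np

__all__ = ["autocorrelation", "integrated_autocorr_time"]


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Sample autocorrelation function of a 1-D series (lag 0 first)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0.0:
        return np.zeros(max_lag + 1)
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    return full / var


def integrated_autocorr_time(x: np.ndarray) -> float:
    """Geyer initial-positive-sequence estimate of tau = 1 + 2 * sum rho_t.

    Pairs of adjacent autocovariances are summed until the first negative
    pair, which truncates the (noisy) tail of the empirical ACF.  tau >= 1;
    the effective sample size of the series is n / tau.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    rho = autocorrelation(x, max_lag=min(n - 2, 1000))
    tau = 1.0
    t = 1
    while t + 1 < len(rho):
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    return max(tau, 1.0)
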