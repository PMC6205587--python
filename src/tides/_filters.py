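"""Shared smoothing helpers: Gaussian-weighted sliding averages."""

from __future__ import annotations

import numpy as np


def silverman_sigma_1d(x) -> float:
    """Classic 1D rule-of-thumb width (4/(3n))^(1/5) * sd, for curve filters."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("cannot choose a filter width for constant values")
    return float((4.0 / (3.0 * n)) ** 0.2 * sd)


def gaussian_weighted_average(eval_at, x, y, sigma: float) -> np.ndarray:
    """Weighted average of y at each eval location, Gaussian in |x - eval|.

    Weights exp(-(x_j - e_l)^2 / sigma^2), renormalized to sum 1 at each
    location, so constants are preserved and end windows are effectively
    truncated-and-renormalized.
    """
    eval_at = np.asarray(eval_at, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.exp(-((x[None, :] - eval_at[:, None]) ** 2) / sigma**2)
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("empty filter window; sigma too small for the grid")
    return (w @ y) / totals


def value_distance_weighted_average(eval_at, x, y, sigma: float) -> np.ndarray:
    """Literal variant: weights measure distance between curve *values*.

    Provided for comparison only — the weights at location l use
    |y_j - y(l)| with y(l) the value nearest to the evaluation point,
    which makes the filter value-adaptive rather than a sliding window.
    """
    eval_at = np.asarray(eval_at, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nearest = np.abs(x[None, :] - eval_at[:, None]).argmin(axis=1)
    ref = y[nearest]
    w = np.exp(-((y[None, :] - ref[:, None]) ** 2) / sigma**2)
    return (w @ y) / w.sum(axis=1)
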