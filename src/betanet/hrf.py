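"""Canonical hemodynamic response model shared by simulation and estimation."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["double_gamma_hrf", "trial_regressor", "stick_regressors"]


def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Positive gamma peaking at ``peak`` s minus ``ratio`` times an
    undershoot gamma peaking at ``undershoot`` s (shape parameters equal
    to the peak times with unit rate), scaled to unit maximum.  Zero for
    t < 0.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, a=peak) - ratio * gamma_dist.pdf(t, a=undershoot)
    h = np.where(t < 0, 0.0, h)
    m = h.max()
    return h / m if m > 0 else h


#: kernel support in seconds; the response is numerically negligible beyond
KERNEL_LENGTH_S = 32.0


def trial_regressor(
    onset: float, tr: float, n_volumes: int,
    kernel_length: float = KERNEL_LENGTH_S, **hrf_kw,
) -> np.ndarray:
    """HRF response to a single impulse event, sampled on the TR grid.

    The kernel is truncated at ``kernel_length`` seconds so regressors
    of well-separated trials have disjoint support.
    """
    times = np.arange(n_volumes) * tr - onset
    h = double_gamma_hrf(times, **hrf_kw)
    return np.where(times > kernel_length, 0.0, h)


def stick_regressors(onsets: np.ndarray, tr: float, n_volumes: int, **hrf_kw) -> np.ndarray:
    """Matrix of per-trial HRF regressors, one column per onset."""
    cols = [trial_regressor(o, tr, n_volumes, **hrf_kw) for o in np.asarray(onsets, float)]
    return np.column_stack(cols) if cols else np.zeros((n_volumes, 0))
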