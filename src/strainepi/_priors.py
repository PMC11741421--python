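"""Shared log-prior terms and their gradients.

Scale parameters are sampled on the log scale; every ``*_logscale`` helper
returns the log density including the Jacobian term and the gradient with
respect to the log-scale parameter.
"""

from __future__ import annotations

import numpy as np


def half_t_logscale(log_sigma: float, df: float, scale: float) -> tuple[float, float]:
    """Half-Student-t(df, 0, scale) prior on sigma = exp(log_sigma)."""
    s2 = np.exp(2.0 * log_sigma)
    denom = df * scale**2 + s2
    lp = -0.5 * (df + 1.0) * np.log1p(s2 / (df * scale**2)) + log_sigma
    grad = -(df + 1.0) * s2 / denom + 1.0
    return lp, grad


def exponential_logscale(log_sigma: float, rate: float) -> tuple[float, float]:
    """Exponential(rate) prior on sigma = exp(log_sigma)."""
    s = np.exp(log_sigma)
    return -rate * s + log_sigma, -rate * s + 1.0


def student_t(x: float, df: float, loc: float, scale: float) -> tuple[float, float]:
    """Student-t(df, loc, scale) prior on an unconstrained location."""
    w = x - loc
    denom = df * scale**2 + w * w
    lp = -0.5 * (df + 1.0) * np.log1p(w * w / (df * scale**2))
    return lp, -(df + 1.0) * w / denom


def half_cauchy_logscale(log_sigma: float, scale: float) -> tuple[float, float]:
    """Half-Cauchy(0, scale) prior on sigma = exp(log_sigma)."""
    q = np.exp(2.0 * (log_sigma - np.log(scale)))
    lp = -np.log1p(q) + log_sigma
    grad = -2.0 * q / (1.0 + q) + 1.0
    return lp, grad


def normal_iid(x: np.ndarray, sd: float) -> tuple[float, np.ndarray]:
    """Independent Normal(0, sd) prior on a vector."""
    return -0.5 * float(x @ x) / sd**2, -x / sd**2
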