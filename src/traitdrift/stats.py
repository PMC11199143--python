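"""Inference utilities: empirical bootstrap CIs, Fisher-z correlation SEs, OLS slope."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "BootstrapCI",
    "bootstrap_variance_ci",
    "correlation_with_fisher_se",
    "regression_coefficient",
]


@dataclasses.dataclass(frozen=True)
class BootstrapCI:
    point_estimate: float
    lower: float
    upper: float
    B: int
    alpha: float
    seed: int | None = None
    method: str = "basic"


def bootstrap_variance_ci(
    values: np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "basic",
) -> BootstrapCI:
    """Bootstrap confidence interval for the variance of ``values``.

    Resamples with replacement ``B`` times and computes the variance of each
    resample.  ``method="basic"`` (the empirical bootstrap) pivots around the
    plug-in variance v: ``[2v - q_{1-a/2}, 2v - q_{a/2}]``; ``"percentile"``
    returns the raw bootstrap quantiles.  A constant input yields the
    degenerate interval [0, 0] with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-d vector of at least 2 values")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    if method not in ("basic", "percentile"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    v_hat = float(np.var(values))
    if v_hat == 0.0:
        warnings.warn("constant input: degenerate bootstrap CI [0, 0]", stacklevel=2)
        return BootstrapCI(0.0, 0.0, 0.0, B=B, alpha=alpha, seed=seed, method=method)
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(B, n))
    boot = np.var(values[idx], axis=1)
    q_lo, q_hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    if method == "basic":
        lower, upper = 2.0 * v_hat - q_hi, 2.0 * v_hat - q_lo
    else:
        lower, upper = q_lo, q_hi
    return BootstrapCI(
        point_estimate=v_hat,
        lower=float(lower),
        upper=float(upper),
        B=B,
        alpha=alpha,
        seed=seed,
        method=method,
    )


def correlation_with_fisher_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a Fisher z-transformation standard error on the r scale.

    z = atanh(r) has se 1/sqrt(n-3); the se is mapped back as
    (tanh(z + se_z) - tanh(z - se_z)) / 2.  At |r| = 1 the se degenerates to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:  # boundary: atanh diverges, se degenerates
        return float(np.sign(r)), 0.0
    z = np.arctanh(r)
    se_z = 1.0 / np.sqrt(n - 3)
    se_r = (np.tanh(z + se_z) - np.tanh(z - se_z)) / 2.0
    return r, float(se_r)


def regression_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant x: slope undefined")
    return float(xc @ (y - y.mean())) / sxx
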