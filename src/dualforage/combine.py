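"""Combining per-session one-tailed p-values into a single per-pair probability.

Pairs observed in several 48-h sessions contribute several session-level
p-values; combining them (rather than pooling windows) avoids
pseudoreplication.  The primary method is Stouffer's Z (sum of standard-normal
upper-tail quantiles rescaled by sqrt(k)); Fisher's chi-square and the logit
method are provided as alternatives and should agree qualitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

METHODS = ("stouffer_z", "fisher", "logit")


@dataclass(frozen=True)
class CombinedP:
    method: str
    statistic: float  # Z, chi-square, or t statistic depending on method
    p_combined: float
    k: int
    pair_id: Optional[str] = None


def clamp_p(p: float, n_iter: int) -> float:
    """Keep Monte Carlo p-values inside (0, 1) for quantile transforms.

    Zeros are clamped to 1/(n_iter+1) and ones to n_iter/(n_iter+1), the
    resolution limits of an ``n_iter``-draw randomization test.
    """
    lo = 1.0 / (n_iter + 1)
    return float(min(max(p, lo), 1.0 - lo))


def _check(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p >= 1)) or not np.all(np.isfinite(p)):
        raise ValueError(
            "p-values must lie strictly in (0,1); clamp Monte Carlo zeros/ones first"
        )
    return p


def combine_stouffer(p_values: Sequence[float], pair_id: Optional[str] = None) -> CombinedP:
    """Z-method: Z = sum(Phi^-1(1-p_i)) / sqrt(k); combined p is the upper tail of Z."""
    p = _check(p_values)
    z = stats.norm.isf(p)
    Z = float(z.sum() / math.sqrt(p.size))
    return CombinedP("stouffer_z", Z, float(stats.norm.sf(Z)), int(p.size), pair_id)


def combine_fisher(p_values: Sequence[float], pair_id: Optional[str] = None) -> CombinedP:
    """Fisher's method: -2 sum(ln p_i) referred to chi-square with 2k df."""
    p = _check(p_values)
    X = float(-2.0 * np.log(p).sum())
    return CombinedP("fisher", X, float(stats.chi2.sf(X, 2 * p.size)), int(p.size), pair_id)


def combine_logit(p_values: Sequence[float], pair_id: Optional[str] = None) -> CombinedP:
    """Logit method: -sum(logit p_i) / sqrt(k pi^2 (5k+2) / (3(5k+4))), t with 5k+4 df."""
    p = _check(p_values)
    k = p.size
    num = float(-np.log(p / (1.0 - p)).sum())
    denom = math.sqrt(k * math.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
    T = num / denom
    return CombinedP("logit", T, float(stats.t.sf(T, 5 * k + 4)), int(k), pair_id)


_COMBINERS = {
    "stouffer_z": combine_stouffer,
    "fisher": combine_fisher,
    "logit": combine_logit,
}


def combine(p_values: Sequence[float], method: str = "stouffer_z",
            pair_id: Optional[str] = None) -> CombinedP:
    if method not in _COMBINERS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return _COMBINERS[method](p_values, pair_id)
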