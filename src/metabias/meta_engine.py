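"""Inverse-variance random-effects meta-analysis with DerSimonian-Laird τ².

Each meta-analysis is re-pooled on the natural-log scale with the
moment-based DerSimonian-Laird estimator of the between-study variance τ²
and normal (z) reference distribution for the pooled CI and p-value — the
default behavior of the review software the source meta-analyses relied on.
Heterogeneity is summarized by Cochran's Q and I² = 100·(Q − df)/Q, both
truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import InsufficientStudiesError, InvalidInputError
from .study_data import LogStats

__all__ = [
    "PooledResult",
    "cochran_q",
    "tau_squared_dl",
    "i_squared",
    "pool_random_effects",
    "wald_p",
]


@dataclass(frozen=True)
class PooledResult:
    """Random-effects synthesis of one meta-analysis (log scale).

    ``ci_lower``/``ci_upper`` are log-scale bounds; exponentiate for the
    ratio scale.  ``i2`` is a percentage in [0, 100].
    """

    k: int
    y_pooled: float
    se_pooled: float
    ci_lower: float
    ci_upper: float
    p_value: float
    q_stat: float
    tau2: float
    i2: float


def _as_arrays(log_stats: Sequence[LogStats]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([ls.y for ls in log_stats], dtype=float)
    s = np.array([ls.s for ls in log_stats], dtype=float)
    return y, s


def wald_p(y: float, s: float) -> float:
    """Two-sided normal p-value for the log effect ``y`` with SE ``s``."""
    if s <= 0.0:
        raise InvalidInputError(f"standard error must be positive, got {s}")
    return float(2.0 * norm.sf(abs(y) / s))


def cochran_q(log_stats: Sequence[LogStats]) -> float:
    """Cochran's heterogeneity statistic Q = Σ wᵢ (yᵢ − ŷ_F)², wᵢ = 1/sᵢ²."""
    if len(log_stats) < 2:
        raise InsufficientStudiesError(f"Q requires k >= 2 studies, got {len(log_stats)}")
    y, s = _as_arrays(log_stats)
    w = 1.0 / s**2
    y_fixed = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - y_fixed) ** 2))


def tau_squared_dl(q: float, weights: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed-effect weights w.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise InsufficientStudiesError(f"DL estimator requires k >= 2 weights, got {w.size}")
    if np.any(w <= 0.0):
        raise InvalidInputError("weights must be positive")
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (w.size - 1)) / denom)


def i_squared(q: float, k: int) -> float:
    """I² heterogeneity percentage, 100·max(0, (Q − (k−1))/Q); 0 when Q = 0."""
    if k < 2:
        raise InsufficientStudiesError(f"I² requires k >= 2, got {k}")
    if q < 0.0:
        raise InvalidInputError(f"Q must be nonnegative, got {q}")
    if q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (q - (k - 1)) / q)


def pool_random_effects(log_stats: Sequence[LogStats]) -> PooledResult:
    """Pool a meta-analysis with random-effects weights w*ᵢ = 1/(sᵢ² + τ²)."""
    k = len(log_stats)
    if k < 2:
        raise InsufficientStudiesError(f"pooling requires k >= 2 studies, got {k}")
    y, s = _as_arrays(log_stats)
    w_fixed = 1.0 / s**2
    q = cochran_q(log_stats)
    tau2 = tau_squared_dl(q, w_fixed)
    w = 1.0 / (s**2 + tau2)
    y_pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = float(np.sum(w) ** -0.5)
    z = float(norm.ppf(0.975))
    return PooledResult(
        k=k,
        y_pooled=y_pooled,
        se_pooled=se_pooled,
        ci_lower=y_pooled - z * se_pooled,
        ci_upper=y_pooled + z * se_pooled,
        p_value=wald_p(y_pooled, se_pooled),
        q_stat=q,
        tau2=tau2,
        i2=i_squared(q, k),
    )
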