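"""Discovery/replication meta-analysis of MR estimates.

Per-target estimates from independent cohorts are pooled by inverse-variance
common-effect weighting, or by a DerSimonian-Laird random-effects model when
Cochran's Q across sources is significant (p <= 0.05; the boundary goes to
random effects).  I² = max(0, (Q - df)/Q) * 100 is reported descriptively
alongside either model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MetaResult:
    model: str          # common | random
    theta: float
    se: float
    pvalue: float
    q: float
    q_p: float
    i2: float           # percent in [0, 100]
    tau2: float
    n_studies: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.theta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.theta + _Z95 * self.se))


def _as_arrays(estimates: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    theta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return theta, se


def _q_stat(theta: np.ndarray, w: np.ndarray) -> tuple[float, float, int]:
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    q_p = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    return q, q_p, df


def i_squared(q: float, df: int) -> float:
    """I² heterogeneity percentage; 0 when Q = 0 or Q <= df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def meta_fixed(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance common-effect pooling."""
    theta, se = _as_arrays(estimates)
    w = se ** -2.0
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q, q_p, df = _q_stat(theta, w)
    i2 = i_squared(q, df) if df >= 1 else 0.0
    p = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult("common", pooled, pooled_se, p, q, q_p, i2, 0.0, len(theta))


def meta_random(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (tau² floored at 0)."""
    theta, se = _as_arrays(estimates)
    n = len(theta)
    if n < 2:
        raise ValueError("random-effects pooling needs at least two studies")
    w = se ** -2.0
    q, q_p, df = _q_stat(theta, w)
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult("random", pooled, pooled_se, p, q, q_p,
                      i_squared(q, df), tau2, n)


def select_and_pool(estimates: Sequence[tuple[float, float]],
                    alpha: float = 0.05) -> MetaResult:
    """Pool with the model chosen by the Q test: common when Q-p > alpha, else random."""
    theta, se = _as_arrays(estimates)
    if len(theta) < 2:
        raise ValueError("model selection needs at least two studies")
    _, q_p, _ = _q_stat(theta, se ** -2.0)
    return meta_fixed(estimates) if q_p > alpha else meta_random(estimates)
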