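"""Rubin's rules for combining estimates and p-values across imputations.

Given per-imputation estimates f_i with variances Var(f_i), the pooled
estimate is the mean f_bar, the within-imputation variance W is the mean
of the Var(f_i), the between-imputation variance is

    B = (1/(m-1)) * sum (f_i - f_bar)^2,    T = W + (1 + 1/m) B,

and Q = f_bar / sqrt(T) is referred to a t distribution with

    nu = (m - 1) * (1 + m W / ((m + 1) B))^2

degrees of freedom.  When all imputations agree (B = 0), nu diverges and
the reference distribution is standard normal.

One-sided exact mid p-values are combined on the probit scale:
z_i = Phi^{-1}(1 - p_i) is N(0,1) under the null, so the same pooling
machinery applies with W = 1.  p-values are clamped away from 0 and 1
before the transform so z_i is always finite.  The deficiency-tail result
is computed and the excess result is derived as its complement, so the
identity p_excess = 1 - p_deficiency holds bit-for-bit, and the two-sided
p-value 2*min(p_deficiency, p_excess) can never exceed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .errors import DomainError

__all__ = ["PooledFResult", "PooledExactResult", "clamp_pvalue",
           "transform_pvalue", "pool_estimates", "pool_z_statistics",
           "pool_exact_pvalues"]

# Below this, between-imputation variance is treated as exactly zero and
# the t reference degenerates to the standard normal.
_B_DEGENERATE = 1e-14

#: Smallest positive normal double: clamp target for p = 0.
EPS_MIN = float(np.finfo(float).tiny)
#: Machine epsilon of 1.0: p is kept below 1 - EPS_ONE.
EPS_ONE = float(np.finfo(float).eps)


@dataclass(frozen=True)
class PooledFResult:
    """Rubin's-rules combination of point estimates (or z statistics)."""

    estimate: float
    W: float
    B: float
    T: float
    nu: float
    Q: float
    p_mi: float
    ci_low: float
    ci_high: float
    m: int


@dataclass(frozen=True)
class PooledExactResult:
    """Pooled one-sided exact mid p-values on the probit scale (W = 1)."""

    z_bar: float
    W: float
    B: float
    T: float
    nu: float
    p_mi_deficiency: float
    p_mi_excess: float
    p_mi_two_sided: float
    m: int


def clamp_pvalue(p: float) -> float:
    """Clamp p into [EPS_MIN, 1 - EPS_ONE] so its probit is finite.

    p = 0 becomes the smallest positive normal double; p with
    1 - p < machine epsilon becomes 1 minus machine epsilon.  Interior
    values pass through unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p-value must lie in [0, 1], got {p}")
    if p < EPS_MIN:
        return EPS_MIN
    if 1.0 - p < EPS_ONE:
        return 1.0 - EPS_ONE
    return p


def transform_pvalue(p: float) -> float:
    """Probit transform z = Phi^{-1}(1 - p), clamped so z is finite."""
    return float(norm.isf(clamp_pvalue(p)))


def _nu(m: int, W: float, B: float) -> float:
    return (m - 1) * (1.0 + m * W / ((m + 1) * B)) ** 2


def _pool(values: np.ndarray, W: float, m: int) -> tuple[float, float, float, float]:
    """Common core: mean, B, T, nu (nu = inf when B degenerates)."""
    mean = float(values.mean())
    B = float(np.sum((values - mean) ** 2) / (m - 1))
    if B < _B_DEGENERATE:
        return mean, 0.0, W, float("inf")
    T = W + (1.0 + 1.0 / m) * B
    return mean, B, T, _nu(m, W, B)


def pool_estimates(
    estimates: Sequence[tuple[float, float]], alpha: float = 0.05
) -> PooledFResult:
    """Pool (estimate, variance) pairs from m >= 2 imputations.

    Returns the pooled estimate, variance components, the test statistic
    Q = f_bar/sqrt(T) with its two-sided p-value against t_nu (standard
    normal when B = 0), and the (1 - alpha) confidence interval
    f_bar +/- t_{nu,1-alpha/2} sqrt(T).
    """
    estimates = list(estimates)
    m = len(estimates)
    if m < 2:
        raise DomainError(
            "pooling requires m >= 2 imputations; "
            "use the single-imputation path for one completed dataset"
        )
    f = np.array([e[0] for e in estimates], dtype=float)
    v = np.array([e[1] for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise DomainError("per-imputation variances must be > 0")
    W = float(v.mean())
    f_bar, B, T, nu = _pool(f, W, m)
    Q = f_bar / np.sqrt(T)
    p_mi = float(2.0 * t_dist.sf(abs(Q), nu))
    tcrit = float(t_dist.ppf(1.0 - alpha / 2.0, nu))
    half = tcrit * np.sqrt(T)
    return PooledFResult(estimate=f_bar, W=W, B=B, T=T, nu=nu, Q=float(Q),
                         p_mi=min(p_mi, 1.0), ci_low=f_bar - half,
                         ci_high=f_bar + half, m=m)


def pool_z_statistics(z_list: Sequence[float], alpha: float = 0.05) -> PooledFResult:
    """Pool signed normal deviates; identical machinery with W = 1."""
    z_list = list(z_list)
    if len(z_list) < 2:
        raise DomainError(
            "pooling requires m >= 2 imputations; "
            "use the single-imputation path for one completed dataset"
        )
    return pool_estimates([(z, 1.0) for z in z_list], alpha=alpha)


def pool_exact_pvalues(p_list: Sequence[float]) -> PooledExactResult:
    """Pool one-sided mid p-values for heterozygote *deficiency*.

    Each p_i is probit-transformed (after clamping), the z_i are pooled
    with W = 1, and the pooled deficiency p-value is the upper t_nu tail
    of z_bar/sqrt(T).  The excess p-value is its complement and the
    two-sided p-value is twice the smaller of the two.
    """
    p_list = list(p_list)
    m = len(p_list)
    if m < 2:
        raise DomainError(
            "pooling requires m >= 2 imputations; "
            "use the single-imputation path for one completed dataset"
        )
    z = np.array([transform_pvalue(p) for p in p_list], dtype=float)
    W = 1.0
    z_bar, B, T, nu = _pool(z, W, m)
    p_def = float(t_dist.sf(z_bar / np.sqrt(T), nu))
    p_exc = 1.0 - p_def
    return PooledExactResult(z_bar=z_bar, W=W, B=B, T=T, nu=nu,
                             p_mi_deficiency=p_def, p_mi_excess=p_exc,
                             p_mi_two_sided=2.0 * min(p_def, p_exc), m=m)
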