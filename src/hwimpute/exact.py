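"""Exact test for Hardy-Weinberg equilibrium at a biallelic marker.

Conditional on the allele count n_A, the number of heterozygotes N_AB under
HWE follows the Levene-Haldane distribution

    P(N_AB = k | N_A = n_A) = n! / (n_AA! k! n_BB!) * 2^k * n_A! n_B! / (2n)!

with n_AA = (n_A - k)/2 and n_BB = (n_B - k)/2, supported on the k between 0
and min(n_A, n_B) that share the parity of n_A.  Standard one-sided p-values
sum the tail including the observed outcome; mid p-values give the observed
outcome half weight, which makes the deficiency and excess p-values exact
complements and keeps every p-value strictly below one for polymorphic
markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .counts import GenotypeCounts
from .errors import DomainError

# Relative tolerance on log-probabilities used when deciding whether two
# support points are "as likely" in the two-sided rules; plain floating
# equality is platform-dependent.
TIE_RTOL = 1e-12

__all__ = ["HetDistribution", "ExactResult", "het_distribution", "exact_test",
           "exact_test_batch"]


@dataclass(frozen=True)
class HetDistribution:
    """Conditional distribution of the heterozygote count given n_A."""

    n: int
    n_A: int
    support: np.ndarray
    prob: np.ndarray

    def pmf(self, k: int) -> float:
        """Probability of observing ``k`` heterozygotes."""
        idx = np.nonzero(self.support == k)[0]
        return float(self.prob[idx[0]]) if idx.size else 0.0


@dataclass(frozen=True)
class ExactResult:
    """Standard and mid p-values of the exact HWE test, both tails."""

    p_deficiency_std: float
    p_excess_std: float
    p_deficiency_mid: float
    p_excess_mid: float
    p_two_sided_std: float
    p_two_sided_mid: float
    prob_observed: float
    monomorphic: bool = False


@lru_cache(maxsize=8192)
def _het_distribution_cached(n: int, n_A: int) -> HetDistribution:
    n_B = 2 * n - n_A
    k_max = min(n_A, n_B)
    support = np.arange(n_A % 2, k_max + 1, 2, dtype=np.int64)
    n_AA = (n_A - support) // 2
    n_BB = (n_B - support) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(support + 1)
        - gammaln(n_BB + 1)
        + support * np.log(2.0)
        + gammaln(n_A + 1)
        + gammaln(n_B + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp)
    total = prob.sum()
    if abs(total - 1.0) > 1e-9:  # should only ever absorb rounding
        raise AssertionError(f"probabilities sum to {total!r}; log-space evaluation failed")
    prob = prob / total
    support.setflags(write=False)
    prob.setflags(write=False)
    return HetDistribution(n=n, n_A=n_A, support=support, prob=prob)


def het_distribution(n: int, n_A: int) -> HetDistribution:
    """Levene-Haldane distribution of the heterozygote count.

    Parameters
    ----------
    n : total sample size (>= 1).
    n_A : count of A alleles, conditioned on; 0 <= n_A <= 2n.

    Evaluated in log space (log-gamma) so sample sizes up to at least 1e5
    are stable; probabilities are renormalized only to absorb rounding at
    the 1e-12 level.
    """
    n = int(n)
    n_A = int(n_A)
    if n < 1:
        raise DomainError(f"sample size n must be >= 1, got {n}")
    if not 0 <= n_A <= 2 * n:
        raise DomainError(f"allele count n_A must satisfy 0 <= n_A <= 2n = {2 * n}, got {n_A}")
    return _het_distribution_cached(n, n_A)


def exact_test(counts: GenotypeCounts) -> ExactResult:
    """Exact HWE test from genotype counts.

    Returns standard and mid p-values for heterozygote deficiency (tail
    toward fewer heterozygotes, observed included), heterozygote excess,
    and the two-sided tests.  The two-sided standard p-value sums the
    probabilities of all outcomes as likely or less likely than the
    observed one; the two-sided mid p-value gives the observed outcome
    half weight and sums only strictly less likely outcomes.

    A monomorphic marker (n_A = 0 or n_B = 0) is not an error: every
    p-value is 1 and ``monomorphic`` is flagged.
    """
    if not isinstance(counts, GenotypeCounts):
        counts = GenotypeCounts(*counts)
    if counts.is_monomorphic:
        return ExactResult(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, prob_observed=1.0,
                           monomorphic=True)

    dist = het_distribution(counts.n, counts.n_A)
    k_obs = counts.n_AB
    support, prob = dist.support, dist.prob
    i_obs = int(np.nonzero(support == k_obs)[0][0])
    p_obs = float(prob[i_obs])

    p_def_std = float(prob[support <= k_obs].sum())
    p_exc_std = float(prob[support >= k_obs].sum())
    p_def_mid = p_def_std - 0.5 * p_obs
    # derived, not recomputed, so the complement identity holds bit-for-bit
    p_exc_mid = 1.0 - p_def_mid

    with np.errstate(divide="ignore"):  # underflowed tail points -> -inf
        logp = np.log(prob)
    log_obs = logp[i_obs]
    tol = TIE_RTOL * max(1.0, abs(log_obs))
    as_or_less_likely = logp <= log_obs + tol
    strictly_less_likely = logp < log_obs - tol
    p_two_std = float(prob[as_or_less_likely].sum())
    p_two_mid = 0.5 * p_obs + float(prob[strictly_less_likely].sum())

    clip = lambda p: min(max(p, 0.0), 1.0)
    return ExactResult(
        p_deficiency_std=clip(p_def_std),
        p_excess_std=clip(p_exc_std),
        p_deficiency_mid=clip(p_def_mid),
        p_excess_mid=clip(p_exc_mid),
        p_two_sided_std=clip(p_two_std),
        p_two_sided_mid=clip(p_two_mid),
        prob_observed=p_obs,
    )


def exact_test_batch(counts_list: Sequence[GenotypeCounts | tuple]) -> list[ExactResult]:
    """Element-wise :func:`exact_test` over a non-empty list, order preserved."""
    counts_list = list(counts_list)
    if not counts_list:
        raise DomainError("exact_test_batch requires a non-empty list of counts")
    return [exact_test(c) for c in counts_list]
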