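"""Inbreeding-coefficient parameterization of Hardy-Weinberg disequilibrium.

Genotype frequencies at a biallelic marker can be written in terms of the
within-population inbreeding coefficient f:

    P_AA = p_A^2 + p_A p_B f,   P_AB = 2 p_A p_B (1 - f),   P_BB = p_B^2 + p_A p_B f

with -p_m/(1 - p_m) <= f <= 1, where p_m is the minor allele frequency.
f = 0 is HWE; f > 0 is a heterozygote deficit, f < 0 an excess.  The ML
estimator from genotype counts is

    f_hat = (4 n_AA n_BB - n_AB^2) / (n_A n_B)

with asymptotic variance

    Var(f_hat) = (1-f)^2 (1-2f)/n + f (1-f)(2-f) / (2 n p_A p_B),

which reduces to 1/n under the null f = 0.  The classical chi-square test
statistic for HWE is X^2 = n f_hat^2 (no continuity correction; the
identity only holds for the uncorrected statistic), and the signed normal
deviate z = sign(f_hat) sqrt(X^2) = sqrt(n) f_hat has unit variance under
the null.

The plug-in variance (f_hat, p_hat substituted into the formula above) is
exposed but is not the default for inference: it is typically below 1/n,
yielding a liberal Wald test, and degenerates to zero at f_hat = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .counts import GenotypeCounts
from .errors import DomainError, MonomorphicMarkerError

__all__ = ["GenotypeModel", "FEstimate", "f_lower_bound", "genotype_freqs",
           "estimate_f", "var_f", "chi2_test", "signed_z"]

_F_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeModel:
    """Genotype probabilities implied by (p_A, f)."""

    p_A: float
    f: float
    P_AA: float
    P_AB: float
    P_BB: float

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.P_AA, self.P_AB, self.P_BB])


@dataclass(frozen=True)
class FEstimate:
    """ML estimate of f with variances and derived test statistics.

    ``var_null`` is 1/n (the variance under H0: f = 0) and is the default
    inferential variance; ``var_plugin`` substitutes the estimates into
    the asymptotic variance formula.  ``boundary_flag`` marks estimates on
    the boundary of the parameter space (no heterozygotes gives f_hat = 1;
    a zero homozygote count gives f_hat = -p_A/(1-p_A) or its mirror).
    """

    f_hat: float
    var_null: float
    var_plugin: float
    chi2: float
    z: float
    boundary_flag: bool
    monomorphic: bool = False
    n: int = 0


def f_lower_bound(p_A: float) -> float:
    """Lower admissible bound of f, -p_m/(1 - p_m)."""
    p_m = min(p_A, 1.0 - p_A)
    if p_m >= 1.0:
        return -1.0
    return -p_m / (1.0 - p_m)


def genotype_freqs(p_A: float, f: float) -> GenotypeModel:
    """Genotype probabilities under the f-parameterized model."""
    if not 0.0 <= p_A <= 1.0:
        raise DomainError(f"allele frequency p_A must lie in [0, 1], got {p_A}")
    lo = f_lower_bound(p_A)
    if f < lo - _F_TOL or f > 1.0 + _F_TOL:
        raise DomainError(
            f"inbreeding coefficient f={f} outside admissible range "
            f"[-p_m/(1-p_m), 1] = [{lo:.6g}, 1]"
        )
    p_B = 1.0 - p_A
    P_AB = max(2.0 * p_A * p_B * (1.0 - f), 0.0)
    P_AA = max(p_A * p_A + p_A * p_B * f, 0.0)
    P_BB = max(p_B * p_B + p_A * p_B * f, 0.0)
    return GenotypeModel(p_A=p_A, f=f, P_AA=P_AA, P_AB=P_AB, P_BB=P_BB)


def var_f(f: float, p_A: float, n: int) -> float:
    """Asymptotic variance of the ML estimator of f; equals 1/n at f = 0."""
    if n < 1:
        raise DomainError(f"sample size n must be >= 1, got {n}")
    if not 0.0 < p_A < 1.0:
        raise DomainError(f"var_f requires 0 < p_A < 1, got {p_A}")
    term1 = (1.0 - f) ** 2 * (1.0 - 2.0 * f) / n
    term2 = f * (1.0 - f) * (2.0 - f) / (2.0 * n * p_A * (1.0 - p_A))
    return term1 + term2


def estimate_f(counts: GenotypeCounts) -> FEstimate:
    """ML estimate of the inbreeding coefficient from genotype counts.

    Monomorphic markers have no defined estimate and return a flagged
    result with NaN fields rather than raising, so batch pipelines can
    keep going.  Integer products are formed in exact arithmetic before
    the final division, so there is no overflow-induced error for n up to
    at least 1e7.
    """
    if not isinstance(counts, GenotypeCounts):
        counts = GenotypeCounts(*counts)
    n = counts.n
    if counts.is_monomorphic:
        nan = float("nan")
        return FEstimate(nan, 1.0 / n, nan, nan, nan,
                         boundary_flag=True, monomorphic=True, n=n)
    num = 4 * counts.n_AA * counts.n_BB - counts.n_AB * counts.n_AB
    den = counts.n_A * counts.n_B
    f_hat = num / den
    boundary = counts.n_AB == 0 or counts.n_AA == 0 or counts.n_BB == 0
    chi2 = n * f_hat * f_hat
    z = math.copysign(math.sqrt(chi2), f_hat)
    return FEstimate(
        f_hat=f_hat,
        var_null=1.0 / n,
        var_plugin=var_f(f_hat, counts.p_A, n),
        chi2=chi2,
        z=z,
        boundary_flag=boundary,
        n=n,
    )


def chi2_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Chi-square test for HWE via X^2 = n f_hat^2, 1 df, upper tail."""
    est = estimate_f(counts)
    if est.monomorphic:
        raise MonomorphicMarkerError(
            "chi-square test undefined for a monomorphic marker (n_A = 0 or n_B = 0)"
        )
    return est.chi2, float(chi2_dist.sf(est.chi2, 1))


def signed_z(counts: GenotypeCounts) -> float:
    """Signed normal deviate z = sign(f_hat) sqrt(X^2) = sqrt(n) f_hat."""
    est = estimate_f(counts)
    if est.monomorphic:
        raise MonomorphicMarkerError(
            "signed z undefined for a monomorphic marker (n_A = 0 or n_B = 0)"
        )
    return est.z
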