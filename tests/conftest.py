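"""Shared fixtures and independent oracles."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import settings

from hwimpute import GenotypeCounts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def levene_haldane_rational(n: int, n_A: int):
    """Rational-arithmetic Levene-Haldane distribution (independent oracle).

    Unnormalized integer weights u(k) = 2^k * n! / (n_AA! k! n_BB!) are
    built with the exact recurrence u(k+2) (k+1)(k+2) = 4 n_AA n_BB u(k),
    then normalized as exact fractions.  Returns (support, [Fraction]).
    """
    n_B = 2 * n - n_A
    k_min = n_A % 2
    k_max = min(n_A, n_B)
    support = list(range(k_min, k_max + 1, 2))
    n_AA0 = (n_A - k_min) // 2
    n_BB0 = (n_B - k_min) // 2
    u = [factorial(n) * 2 ** k_min // (factorial(k_min) * factorial(n_AA0) * factorial(n_BB0))]
    for k in support[:-1]:
        n_AA = (n_A - k) // 2
        n_BB = (n_B - k) // 2
        u.append(u[-1] * 4 * n_AA * n_BB // ((k + 1) * (k + 2)))
    total = sum(u)
    return support, [Fraction(w, total) for w in u]


def exact_test_rational(n_AA: int, n_AB: int, n_BB: int):
    """Brute-force exact-test p-values in rational arithmetic.

    Returns a dict with one-sided (deficiency/excess) standard and mid
    p-values and both two-sided conventions, all as Fractions.
    """
    n = n_AA + n_AB + n_BB
    n_A = 2 * n_AA + n_AB
    support, prob = levene_haldane_rational(n, n_A)
    p = dict(zip(support, prob))
    p_obs = p[n_AB]
    p_def = sum(v for k, v in p.items() if k <= n_AB)
    p_exc = sum(v for k, v in p.items() if k >= n_AB)
    half = Fraction(1, 2) * p_obs
    return {
        "p_deficiency_std": p_def,
        "p_excess_std": p_exc,
        "p_deficiency_mid": p_def - half,
        "p_excess_mid": p_exc - half,
        "p_two_sided_std": sum(v for v in p.values() if v <= p_obs),
        "p_two_sided_mid": half + sum(v for v in p.values() if v < p_obs),
        "prob_observed": p_obs,
    }


def random_polymorphic_counts(rng: np.random.Generator, max_n: int = 200) -> GenotypeCounts:
    """A random genotype-count triple guaranteed polymorphic."""
    while True:
        n = int(rng.integers(2, max_n + 1))
        c = rng.multinomial(n, rng.dirichlet([1.0, 1.0, 1.0]))
        counts = GenotypeCounts(*(int(v) for v in c))
        if not counts.is_monomorphic:
            return counts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150915)


# Published genotype counts of four SNP-array markers with a high missing
# rate, with the inbreeding coefficients and two-sided exact mid p-values
# obtained when missing genotypes are discarded.
TABLE1 = [
    ("rs818284", (1593, 138, 67), 0.451, 0.000),
    ("rs13022866", (788, 781, 237), 0.046, 0.046),
    ("rs3766263", (533, 865, 277), -0.058, 0.020),
    ("rs2714888", (1092, 499, 69), 0.031, 0.192),
]


@pytest.fixture
def table1():
    return TABLE1
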