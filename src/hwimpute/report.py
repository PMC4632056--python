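"""Reporting helpers: QQ-plot data, ternary coordinates, acceptance region.

The ternary plot places the genotype composition (P_AA, P_AB, P_BB) in
barycentric coordinates with the AA vertex at the origin, the BB vertex
at (1, 0) and the AB (heterozygote) vertex at the apex, so the vertical
axis is proportional to the heterozygote fraction.  Under HWE the
compositions trace the parabola P_AB = 2 sqrt(P_AA P_BB); the chi-square
acceptance region at level alpha is the band swept by the model
compositions with |f| <= f_crit = sqrt(chi2_{1,1-alpha}/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .errors import DomainError
from .inbreeding import f_lower_bound, genotype_freqs

__all__ = ["TernaryPoint", "qq_data", "ternary_coordinates",
           "acceptance_region", "f_critical"]

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class TernaryPoint:
    """Plane coordinates of one genotype composition."""

    x: float
    y: float
    significant: Optional[bool] = None


def qq_data(p_values: Sequence[float]) -> pd.DataFrame:
    """(expected, observed) -log10 quantile pairs for a QQ plot.

    Observed p-values are sorted and set against uniform plotting
    positions i/(k+1).  Clamped inputs (p = 0) stay finite because the
    smallest representable positive p has a finite -log10.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise DomainError("qq_data requires a non-empty p-value list")
    tiny = float(np.finfo(float).tiny)
    obs = -np.log10(np.clip(np.sort(p)[::-1], tiny, 1.0))  # ascending -log10
    k = p.size
    exp = -np.log10(np.arange(k, 0, -1) / (k + 1.0))
    return pd.DataFrame({"expected": exp, "observed": obs})


def ternary_coordinates(compositions: Sequence[Sequence[float]],
                        significant: Optional[Sequence[bool]] = None
                        ) -> list[TernaryPoint]:
    """Barycentric plane coordinates of genotype compositions.

    (1,0,0) maps to the left vertex (0,0), (0,1,0) to the apex
    (1/2, sqrt(3)/2), (0,0,1) to the right vertex (1,0).
    """
    out = []
    for i, comp in enumerate(compositions):
        a, b, c = (float(v) for v in comp)
        if abs(a + b + c - 1.0) > 1e-9:
            raise DomainError(
                f"composition {i} sums to {a + b + c!r}, not 1 (tolerance 1e-9)")
        if min(a, b, c) < -1e-12:
            raise DomainError(f"composition {i} has a negative component")
        sig = None if significant is None else bool(significant[i])
        out.append(TernaryPoint(x=c + 0.5 * b, y=_SQRT3_2 * b, significant=sig))
    return out


def f_critical(n: int, alpha: float = 0.05) -> float:
    """|f_hat| above which the chi-square HWE test rejects at level alpha."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    return math.sqrt(chi2_dist.ppf(1.0 - alpha, 1) / n)


def acceptance_region(n: int, alpha: float = 0.05, grid: int = 401
                      ) -> tuple[list[TernaryPoint], list[TernaryPoint]]:
    """Upper and lower boundary curves of the chi-square acceptance region.

    For a grid of allele frequencies, the curves are the compositions of
    the genotype model at f = +f_crit (heterozygote-deficit side) and
    f = max(-f_crit, lower admissible bound); a sample is significant at
    level alpha exactly when its composition falls outside the band.
    """
    fc = min(f_critical(n, alpha), 1.0)
    p_grid = np.linspace(0.0, 1.0, grid)[1:-1]
    upper, lower = [], []
    for p in p_grid:
        upper.append(genotype_freqs(p, fc).probs)
        lower.append(genotype_freqs(p, max(-fc, f_lower_bound(p))).probs)
    return ternary_coordinates(upper), ternary_coordinates(lower)
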