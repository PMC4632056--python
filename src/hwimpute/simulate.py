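"""Synthetic marker panels with the structure the analysis assumes.

Genotypes are drawn i.i.d. from the f-parameterized model; flanking
markers copy the target genotype with probability ``ld_r`` and are
resampled from the target's marginal otherwise, which gives a single
interpretable linkage-disequilibrium knob; two-channel allele
intensities come from Gaussian clusters per genotype, with an optional
near-origin cluster for null-allele carriers; missingness is missing
completely at random (MCAR), heterozygote-biased, or driven by a latent
null allele whose carriers fail to hybridize.

Defaults mirror a SNP-array cohort of 1939 samples and 677 markers with
allele frequencies drawn uniformly and a 5% missing rate, the regime in
which imputation-aware HWE testing is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .counts import AA, AB, BB, MISSING
from .errors import DomainError
from .imputation import MarkerDataset
from .inbreeding import genotype_freqs

__all__ = ["NoMissing", "Mcar", "HetBiased", "NullAllele", "IntensityParams",
           "SimulationConfig", "sim_genotypes", "sim_flanking",
           "sim_intensities", "sim_missingness", "sim_marker", "sim_panel"]


@dataclass(frozen=True)
class NoMissing:
    """Fully observed marker."""


@dataclass(frozen=True)
class Mcar:
    """Each entry missing independently with probability ``rate``."""

    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise DomainError(f"MCAR rate must lie in [0, 1], got {self.rate}")


@dataclass(frozen=True)
class HetBiased:
    """Heterozygotes missing at base_rate * het_multiplier, homozygotes at base_rate."""

    base_rate: float
    het_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise DomainError(f"base_rate must lie in [0, 1], got {self.base_rate}")
        if self.het_multiplier < 1.0:
            raise DomainError(f"het_multiplier must be >= 1, got {self.het_multiplier}")
        if self.base_rate * self.het_multiplier > 1.0:
            raise DomainError("base_rate * het_multiplier exceeds 1")


@dataclass(frozen=True)
class NullAllele:
    """Latent null-allele carriers (probability ``carrier_freq``) are all missing."""

    carrier_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise DomainError(f"carrier_freq must lie in [0, 1], got {self.carrier_freq}")


Mechanism = Union[NoMissing, Mcar, HetBiased, NullAllele]


@dataclass(frozen=True)
class IntensityParams:
    """2-D Gaussian cluster parameters per genotype, plus the null cluster.

    Default geometry follows a two-channel SNP array: AA high on channel
    x, BB high on channel y, AB in between, null-allele carriers near the
    origin with approximately zero intensities.
    """

    means: tuple[tuple[float, float], ...] = ((1.0, 0.1), (0.6, 0.6), (0.1, 1.0))
    sds: tuple[float, float, float] = (0.15, 0.15, 0.15)
    null_mean: tuple[float, float] = (0.02, 0.02)
    null_sd: float = 0.02


@dataclass
class SimulationConfig:
    """Panel-level simulation settings.

    ``p_A`` may be a fixed frequency or a callable ``f(rng) -> float``
    drawn once per marker (default: uniform on [0.05, 0.95], i.e. no
    minor-allele-frequency threshold beyond avoiding near-fixed alleles).
    """

    n: int = 1939
    m_markers: int = 677
    p_A: Union[float, Callable[[np.random.Generator], float], None] = None
    f: float = 0.0
    missing_mechanism: Mechanism = field(default_factory=lambda: Mcar(0.05))
    ld_r: float = 0.8
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if self.m_markers < 1:
            raise DomainError(f"m_markers must be >= 1, got {self.m_markers}")
        if not 0.0 <= self.ld_r <= 1.0:
            raise DomainError(f"ld_r must lie in [0, 1], got {self.ld_r}")

    def draw_p_A(self, rng: np.random.Generator) -> float:
        if self.p_A is None:
            return float(rng.uniform(0.05, 0.95))
        if callable(self.p_A):
            return float(self.p_A(rng))
        return float(self.p_A)


def sim_genotypes(n: int, p_A: float, f: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. genotypes from the f-parameterized model (0/1/2 coding)."""
    model = genotype_freqs(p_A, f)  # validates admissibility of (p_A, f)
    return rng.choice(3, size=n, p=model.probs / model.probs.sum()).astype(np.int8)


def sim_flanking(genotypes: np.ndarray, ld_r: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two flanking genotype vectors correlated with the target.

    Each flank entry copies the target genotype with probability ``ld_r``
    and is otherwise resampled from the target's empirical marginal;
    ld_r = 1 duplicates the target, ld_r = 0 gives independence.
    """
    if not 0.0 <= ld_r <= 1.0:
        raise DomainError(f"ld_r must lie in [0, 1], got {ld_r}")
    g = np.asarray(genotypes, dtype=np.int8)
    n = len(g)
    flanks = []
    for _ in range(2):
        copy = rng.random(n) < ld_r
        resampled = g[rng.integers(0, n, size=n)]
        flanks.append(np.where(copy, g, resampled).astype(np.int8))
    return flanks[0], flanks[1]


def sim_intensities(genotypes: np.ndarray, params: IntensityParams,
                    rng: np.random.Generator,
                    null_carriers: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Two-channel intensities: per-genotype Gaussian clusters.

    ``null_carriers`` marks samples drawn from the near-origin null
    cluster regardless of genotype.
    """
    g = np.asarray(genotypes)
    n = len(g)
    x = np.empty(n)
    y = np.empty(n)
    for code, (mean, sd) in enumerate(zip(params.means, params.sds)):
        sel = g == code
        k = int(sel.sum())
        x[sel] = mean[0] + sd * rng.standard_normal(k)
        y[sel] = mean[1] + sd * rng.standard_normal(k)
    if null_carriers is not None and np.any(null_carriers):
        k = int(np.sum(null_carriers))
        x[null_carriers] = params.null_mean[0] + params.null_sd * rng.standard_normal(k)
        y[null_carriers] = params.null_mean[1] + params.null_sd * rng.standard_normal(k)
    return pd.DataFrame({"intensity_x": x, "intensity_y": y})


def sim_missingness(genotypes: np.ndarray, mechanism: Mechanism,
                    rng: np.random.Generator) -> np.ndarray:
    """Boolean missing mask under the configured mechanism.

    For :class:`NullAllele` the mask is the latent carrier indicator (all
    carriers fail); use :func:`sim_marker` to keep the carrier set
    consistent with the intensity clusters.
    """
    g = np.asarray(genotypes)
    n = len(g)
    if isinstance(mechanism, NoMissing):
        return np.zeros(n, dtype=bool)
    if isinstance(mechanism, Mcar):
        return rng.random(n) < mechanism.rate
    if isinstance(mechanism, HetBiased):
        rate = np.where(g == AB, mechanism.base_rate * mechanism.het_multiplier,
                        mechanism.base_rate)
        return rng.random(n) < rate
    if isinstance(mechanism, NullAllele):
        return rng.random(n) < mechanism.carrier_freq
    raise DomainError(f"unknown missingness mechanism {mechanism!r}")


def sim_marker(config: SimulationConfig, rng: np.random.Generator,
               marker_id: str = "sim1", p_A: Optional[float] = None,
               pos: Optional[int] = None) -> MarkerDataset:
    """One marker with genotypes, flanks, intensities, and missingness."""
    if p_A is None:
        p_A = config.draw_p_A(rng)
    g_true = sim_genotypes(config.n, p_A, config.f, rng)
    left, right = sim_flanking(g_true, config.ld_r, rng)
    mask = sim_missingness(g_true, config.missing_mechanism, rng)
    null_carriers = mask if isinstance(config.missing_mechanism, NullAllele) else None
    inten = sim_intensities(g_true, config.intensity_params, rng,
                            null_carriers=null_carriers)
    g_obs = g_true.copy()
    g_obs[mask] = MISSING
    cov = pd.DataFrame({"left_flank": left, "right_flank": right})
    cov = pd.concat([cov, inten], axis=1)
    ds = MarkerDataset(marker_id=marker_id, genotypes=g_obs, covariates=cov,
                       contig="1", pos=pos)
    ds.true_genotypes = g_true  # type: ignore[attr-defined]
    ds.true_f = config.f  # type: ignore[attr-defined]
    ds.true_p_A = p_A  # type: ignore[attr-defined]
    return ds


def sim_panel(config: SimulationConfig) -> list[MarkerDataset]:
    """Independent markers per the config; bit-identical under a fixed seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.m_markers)
    panel = []
    for j, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        panel.append(sim_marker(config, rng, marker_id=f"sim{j + 1}",
                                pos=(j + 1) * 100_000))
    return panel
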