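"""Per-marker HWE analysis under discarding, single and multiple imputation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .counts import GenotypeCounts
from .exact import exact_test
from .errors import HwimputeError
from .imputation import (MarkerDataset, derive_marker_seed,
                         impute_with_fallback, single_impute)
from .inbreeding import estimate_f
from .pooling import pool_estimates, pool_exact_pvalues
from scipy.stats import chi2 as _chi2_dist

logger = logging.getLogger("hwimpute")

NAN = float("nan")

__all__ = ["PipelineConfig", "MarkerResultRow", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for :func:`run_pipeline`.

    ``method``: which paths to run — discard, single, multi, or all.
    ``m``: imputations per marker (50 by default).  ``variance``: per-
    imputation variance for f-pooling, 'null' (1/n) or 'plugin'.
    ``si_mode``: best_guess or random for the internal single-imputation
    path; an externally completed dataset can be passed per marker via
    ``completed``.
    """

    method: str = "all"
    m: int = 50
    seed: int = 0
    alpha: float = 0.05
    covariates: str = "auto"
    variance: str = "null"
    si_mode: str = "best_guess"

    def __post_init__(self) -> None:
        if self.method not in ("discard", "single", "multi", "all"):
            raise HwimputeError(f"unknown method '{self.method}'")
        if self.variance not in ("null", "plugin"):
            raise HwimputeError(f"unknown variance option '{self.variance}'")


@dataclass
class MarkerResultRow:
    """One output row per input marker; failures are flagged, not dropped."""

    marker_id: str
    n_AA: int = 0
    n_AB: int = 0
    n_BB: int = 0
    n_missing: int = 0
    f_discard: float = NAN
    f_si: float = NAN
    f_mi: float = NAN
    p_exact_discard_two_sided: float = NAN
    p_chi2_discard: float = NAN
    p_si_chi2: float = NAN
    p_si_exact_two_sided: float = NAN
    p_mi_chi2: float = NAN
    p_mi_exact_two_sided: float = NAN
    model_used: str = "NA"
    monomorphic: bool = False
    boundary: bool = False
    inestimable: bool = False
    error: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _chi2_p(counts: GenotypeCounts) -> float:
    est = estimate_f(counts)
    if est.monomorphic:
        return NAN
    return float(_chi2_dist.sf(est.chi2, 1))


def _analyze_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    """(f_hat, two-sided exact mid p, chi2 p) for one completed dataset."""
    est = estimate_f(counts)
    ex = exact_test(counts)
    return est.f_hat, ex.p_two_sided_mid, _chi2_p(counts)


def run_pipeline(datasets: Sequence[MarkerDataset], config: PipelineConfig,
                 completed: Optional[dict[str, np.ndarray]] = None) -> list[MarkerResultRow]:
    """Run the configured analysis paths over a batch of markers.

    ``completed`` optionally maps marker ids to externally completed
    genotype vectors for the single-imputation path.  The batch never
    aborts: per-marker failures produce flagged rows.
    """
    rows = []
    for ds in datasets:
        row = MarkerResultRow(marker_id=ds.marker_id)
        try:
            _analyze_marker(ds, config, row, completed)
        except HwimputeError as err:  # pragma: no cover - defensive
            row.error = str(err)
            logger.warning("marker %s failed: %s", ds.marker_id, err)
        rows.append(row)
    return rows


def _fallback_order(config: PipelineConfig, ds: MarkerDataset) -> tuple[str, ...]:
    if config.covariates == "flanking":
        return ("flanking", "marginal")
    if config.covariates == "intensities":
        return ("intensities", "marginal")
    return ("flanking", "intensities", "flanking+intensities", "marginal")


def _analyze_marker(ds: MarkerDataset, config: PipelineConfig,
                    row: MarkerResultRow,
                    completed: Optional[dict[str, np.ndarray]]) -> None:
    counts = ds.observed_counts()
    row.n_AA, row.n_AB, row.n_BB = counts.as_tuple()
    row.n_missing = ds.n_missing
    row.monomorphic = counts.is_monomorphic

    est = estimate_f(counts)
    row.f_discard = est.f_hat
    row.boundary = est.boundary_flag and not est.monomorphic
    ex = exact_test(counts)
    row.p_exact_discard_two_sided = ex.p_two_sided_mid
    row.p_chi2_discard = _chi2_p(counts)

    marker_seed = derive_marker_seed(config.seed, ds.marker_id)

    if config.method in ("single", "all"):
        vec = completed.get(ds.marker_id) if completed else None
        if vec is not None:
            si = single_impute(ds, "external", completed=vec)
        else:
            si = single_impute(ds, config.si_mode, seed=marker_seed)
        c = GenotypeCounts.from_genotypes(si)
        row.f_si, row.p_si_exact_two_sided, row.p_si_chi2 = _analyze_counts(c)

    if config.method in ("multi", "all"):
        imp = impute_with_fallback(ds, m=config.m, seed=marker_seed,
                                   order=_fallback_order(config, ds))
        row.model_used = imp.model_used
        row.inestimable = imp.inestimable_flag
        if imp.inestimable_flag:
            return
        ests = []
        p_def = []
        for c in imp.counts:
            e = estimate_f(c)
            var = e.var_null if config.variance == "null" else e.var_plugin
            ests.append((e.f_hat, var))
            p_def.append(exact_test(c).p_deficiency_mid)
        pooled_f = pool_estimates(ests, alpha=config.alpha)
        pooled_p = pool_exact_pvalues(p_def)
        row.f_mi = pooled_f.estimate
        row.p_mi_chi2 = pooled_f.p_mi
        row.p_mi_exact_two_sided = pooled_p.p_mi_two_sided
        logger.info("marker %s: method=multi model_used=%s seed=%d fallbacks=%s",
                    ds.marker_id, imp.model_used, marker_seed,
                    "; ".join(imp.warnings) or "none")
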