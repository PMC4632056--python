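"""Multinomial-logit imputation of missing genotypes, MICE-style.

One incomplete target marker is imputed from covariates observed on the
same samples: genotypes of the two flanking markers (entered as
categorical indicators, two columns per flank), two-channel allele
intensities, or both.  A multinomial logit of the genotype category on
the covariates is fitted to the complete cases; each imputation round
draws a coefficient vector from the asymptotic normal approximation to
the fit's posterior, computes per-sample category probabilities for the
missing entries, and samples one genotype per entry.  With a single
incomplete variable and complete covariates no chaining is needed, so
one draw per round yields proper imputations.

When the model cannot be estimated (response without variation,
covariates missing for the samples to be imputed, perfect separation),
:func:`impute_with_fallback` walks the covariate sets
flanking -> intensities -> flanking+intensities -> marginal; the
marginal fallback draws genotype probabilities from a Dirichlet over the
observed category counts and always succeeds for polymorphic data.  The
model can only impute categories observed in the data; when one
homozygote is entirely unobserved, its genotype is never imputed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counts import AA, AB, BB, MISSING, GenotypeCounts
from .errors import DomainError, InestimableModelError

__all__ = ["MarkerDataset", "ImputationSet", "FittedImputationModel",
           "fit_imputation_model", "draw_imputations", "impute_with_fallback",
           "single_impute", "derive_marker_seed"]

FLANK_COLUMNS = ("left_flank", "right_flank")
INTENSITY_COLUMNS = ("intensity_x", "intensity_y")

COVARIATE_SPECS = ("flanking", "intensities", "flanking+intensities")
FALLBACK_ORDER = ("flanking", "intensities", "flanking+intensities", "marginal")


@dataclass
class MarkerDataset:
    """Per-sample genotypes of one marker plus optional covariates.

    ``genotypes`` is an integer vector coded 0 (AA), 1 (AB), 2 (BB) with
    -1 for missing.  ``covariates`` may carry columns ``left_flank`` and
    ``right_flank`` (same coding) and ``intensity_x``/``intensity_y``
    (floats, NaN for missing).
    """

    marker_id: str
    genotypes: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    contig: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.covariates is not None and len(self.covariates) != len(self.genotypes):
            raise DomainError(
                f"marker {self.marker_id}: covariate table has "
                f"{len(self.covariates)} rows for {len(self.genotypes)} samples"
            )
        if not np.any(self.genotypes != MISSING):
            raise DomainError(f"marker {self.marker_id}: no non-missing genotype")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def observed_counts(self) -> GenotypeCounts:
        return GenotypeCounts.from_genotypes(self.genotypes)


@dataclass
class ImputationSet:
    """m completed genotype vectors for one marker, with provenance."""

    marker_id: str
    completed: np.ndarray  # (m, n_samples) int8, no MISSING entries
    m: int
    seed: int
    model_used: str  # flanking | intensities | flanking+intensities | marginal
    inestimable_flag: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def counts(self) -> list[GenotypeCounts]:
        return [GenotypeCounts.from_genotypes(v) for v in self.completed]


#: Prior standard deviation of the weakly-informative Gaussian prior on the
#: logit coefficients (ridge penalty lambda = 1/PRIOR_SD**2).  Stabilizes the
#: fit under quasi-separation, which is routine when categorical flanking
#: predictors leave sparse cells.
PRIOR_SD = 2.5


@dataclass
class FittedImputationModel:
    """A multinomial-logit fit of genotype on covariates (complete cases).

    The coefficients are the posterior mode under independent N(0, PRIOR_SD^2)
    priors, with the Laplace (inverse penalized information) covariance used
    for the posterior draws of proper multiple imputation.
    """

    params: np.ndarray  # (k_exog, J-1) baseline-category coefficients
    cov_params: np.ndarray  # covariance of params.ravel(order='F')
    categories: np.ndarray  # observed genotype codes, ascending
    columns: list[str]  # design columns after the constant
    covariate_spec: str
    n_complete: int

    def design_for(self, data: MarkerDataset, rows: np.ndarray) -> np.ndarray:
        X = _design_matrix(data, self.covariate_spec)
        if np.any(~np.isfinite(X[rows])):
            raise InestimableModelError(
                f"marker {data.marker_id}: covariates missing for samples to impute"
            )
        return X[rows]

    def predict_proba(self, X: np.ndarray, params: Optional[np.ndarray] = None) -> np.ndarray:
        """Category probabilities; ``params`` overrides the fitted coefficients."""
        beta = self.params if params is None else params
        eta = X @ beta
        full = np.column_stack([np.zeros(len(X)), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)


def derive_marker_seed(master_seed: int, marker_id: str) -> int:
    """Stable per-marker seed from (master seed, marker id).

    A keyed hash makes marker-level results reproducible independently of
    batch order.
    """
    h = hashlib.blake2b(f"{master_seed}:{marker_id}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


def _design_matrix(data: MarkerDataset, covariate_spec: str) -> np.ndarray:
    """Design matrix (constant first); rows with missing covariates are NaN."""
    cov = data.covariates
    cols: list[np.ndarray] = []
    use_flank = covariate_spec in ("flanking", "flanking+intensities")
    use_inten = covariate_spec in ("intensities", "flanking+intensities")
    if cov is None:
        raise InestimableModelError(
            f"marker {data.marker_id}: no covariates supplied for spec '{covariate_spec}'"
        )
    if use_flank:
        for name in FLANK_COLUMNS:
            if name not in cov.columns:
                raise InestimableModelError(
                    f"marker {data.marker_id}: covariate column '{name}' absent"
                )
            g = np.asarray(cov[name], dtype=float)
            g[np.asarray(cov[name]) == MISSING] = np.nan
            # two indicator columns per flank (AB, BB); AA is the base level
            for level in (AB, BB):
                ind = np.where(np.isnan(g), np.nan, (g == level).astype(float))
                cols.append(ind)
    if use_inten:
        for name in INTENSITY_COLUMNS:
            if name not in cov.columns:
                raise InestimableModelError(
                    f"marker {data.marker_id}: covariate column '{name}' absent"
                )
            cols.append(np.asarray(cov[name], dtype=float))
    X = np.column_stack(cols)
    return np.column_stack([np.ones(len(X)), X])


def fit_imputation_model(data: MarkerDataset, covariate_spec: str) -> FittedImputationModel:
    """Fit a multinomial logit of genotype on covariates, complete cases only.

    Raises :class:`InestimableModelError` when the observed response shows
    no variation, when covariates are missing for the samples that need
    imputation, when no covariate varies on the complete cases, or when
    the fit is degenerate (perfect separation / singular information).
    """
    if covariate_spec not in COVARIATE_SPECS:
        raise DomainError(f"unknown covariate spec '{covariate_spec}'")
    g = data.genotypes
    observed = g != MISSING
    categories = np.unique(g[observed])
    if len(categories) < 2:
        raise InestimableModelError(
            f"marker {data.marker_id}: the response shows no variation"
        )
    X_all = _design_matrix(data, covariate_spec)
    cov_ok = np.all(np.isfinite(X_all), axis=1)
    need = data.missing_mask
    if need.any() and not cov_ok[need].all():
        raise InestimableModelError(
            f"marker {data.marker_id}: covariates missing for the same "
            f"individuals as the target"
        )
    cc = observed & cov_ok
    Xcc = X_all[cc]
    # drop non-varying columns (keep the constant)
    keep = [0] + [j for j in range(1, Xcc.shape[1]) if np.ptp(Xcc[:, j]) > 0]
    if len(keep) < 2:
        raise InestimableModelError(
            f"marker {data.marker_id}: no covariate with variation on the complete cases"
        )
    Xcc = Xcc[:, keep]
    code = np.searchsorted(categories, g[cc])
    try:
        params, cov = _penalized_mnlogit(code, Xcc, lam=1.0 / PRIOR_SD**2)
    except Exception as err:
        raise InestimableModelError(
            f"marker {data.marker_id}: multinomial logit inestimable ({err})"
        ) from err
    # perfect separation: the covariates classify every complete case with
    # near-certainty, so the unpenalized likelihood has no interior maximum
    fitted = np.column_stack([np.zeros(len(Xcc)), Xcc @ params])
    fitted -= fitted.max(axis=1, keepdims=True)
    prob_cc = np.exp(fitted)
    prob_cc /= prob_cc.sum(axis=1, keepdims=True)
    if float(prob_cc[np.arange(len(code)), code].min()) > 0.95:
        raise InestimableModelError(
            f"marker {data.marker_id}: perfect separation between genotype "
            f"and covariates"
        )
    model = FittedImputationModel(params=params, cov_params=cov,
                                  categories=categories,
                                  columns=[f"x{j}" for j in keep[1:]],
                                  covariate_spec=covariate_spec,
                                  n_complete=int(cc.sum()))
    model._keep = keep  # type: ignore[attr-defined]
    return model


def _penalized_mnlogit(code: np.ndarray, X: np.ndarray,
                       lam: float, maxiter: int = 100,
                       tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized multinomial-logit fit by Newton with step halving.

    Maximizes loglike(theta) - lam/2 ||theta||^2 (the posterior mode under
    N(0, 1/lam) coefficient priors); the penalized objective is strictly
    concave, so the fit exists even under separation.  Returns the (K, J-1)
    coefficient matrix and the Laplace covariance of theta (F-ordered).
    """
    model = sm.MNLogit(code, X)
    K = X.shape[1]
    Jm1 = int(code.max())
    dim = K * Jm1
    theta = np.zeros(dim)
    eye = np.eye(dim)
    obj = model.loglike(theta) - 0.5 * lam * theta @ theta
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(maxiter):
            grad = model.score(theta) - lam * theta
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            hess = model.hessian(theta) - lam * eye
            step = np.linalg.solve(hess, grad)
            t = 1.0
            while t > 1e-6:
                cand = theta - t * step
                obj_cand = model.loglike(cand) - 0.5 * lam * cand @ cand
                if obj_cand >= obj - 1e-12:
                    break
                t /= 2.0
            theta, obj = cand, obj_cand
    if not converged or not np.all(np.isfinite(theta)):
        raise np.linalg.LinAlgError("penalized Newton did not converge")
    cov = np.linalg.inv(-(model.hessian(theta) - lam * eye))
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)):
        raise np.linalg.LinAlgError("singular penalized information")
    return theta.reshape(K, Jm1, order="F"), cov


def _model_design_rows(model: FittedImputationModel, data: MarkerDataset,
                       rows: np.ndarray) -> np.ndarray:
    X = model.design_for(data, rows)
    return X[:, model._keep]  # type: ignore[attr-defined]


def _sample_categories(prob: np.ndarray, categories: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(prob))
    cum = np.cumsum(prob, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return categories[np.minimum(idx, len(categories) - 1)]


def draw_imputations(model: FittedImputationModel, data: MarkerDataset,
                     m: int, seed: int) -> ImputationSet:
    """Draw m completed genotype vectors under the fitted model.

    Each round draws a coefficient vector from N(beta_hat, Cov(beta_hat))
    (parameter uncertainty), recomputes category probabilities for the
    missing entries, and samples genotypes.  Deterministic given ``seed``;
    with no missing entries the draw step is a no-op.
    """
    if m < 1:
        raise DomainError(f"number of imputations m must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    miss = np.nonzero(data.missing_mask)[0]
    completed = np.tile(data.genotypes, (m, 1)).astype(np.int8)
    if len(miss):
        params = model.params  # (K, J-1)
        cov = model.cov_params  # order matches ravel(order='F')
        mean = params.ravel(order="F")
        Xmiss = _model_design_rows(model, data, miss)
        for i in range(m):
            beta = rng.multivariate_normal(mean, cov, method="svd")
            beta = beta.reshape(params.shape, order="F")
            prob = model.predict_proba(Xmiss, params=beta)
            completed[i, miss] = _sample_categories(prob, model.categories, rng)
    return ImputationSet(marker_id=data.marker_id, completed=completed, m=m,
                         seed=seed, model_used=model.covariate_spec)


def _marginal_imputations(data: MarkerDataset, m: int, seed: int) -> ImputationSet:
    """Proper marginal fallback: Dirichlet draw over observed category counts."""
    rng = np.random.default_rng(seed)
    g = data.genotypes
    observed = g != MISSING
    cats, cnt = np.unique(g[observed], return_counts=True)
    miss = np.nonzero(~observed)[0]
    completed = np.tile(g, (m, 1)).astype(np.int8)
    warn: list[str] = []
    inestimable = False
    if len(cats) < 2:
        inestimable = True
        warn.append(f"marker {data.marker_id}: monomorphic observed response; "
                    f"missing entries filled with the single observed genotype")
        completed[:, miss] = cats[0]
    elif len(miss):
        for i in range(m):
            p = rng.dirichlet(cnt.astype(float))
            completed[i, miss] = _sample_categories(
                np.tile(p, (len(miss), 1)), cats, rng)
    return ImputationSet(marker_id=data.marker_id, completed=completed, m=m,
                         seed=seed, model_used="marginal",
                         inestimable_flag=inestimable, warnings=warn)


def impute_with_fallback(data: MarkerDataset, m: int, seed: int,
                         order: Sequence[str] = FALLBACK_ORDER) -> ImputationSet:
    """Impute trying covariate sets in order; record which one was used.

    Default order: flanking -> intensities -> flanking+intensities ->
    marginal.  The marginal fallback always succeeds; for a monomorphic
    observed response it fills the single observed category and flags the
    result inestimable.
    """
    notes: list[str] = []
    for spec in order:
        if spec == "marginal":
            out = _marginal_imputations(data, m, seed)
            out.warnings = notes + out.warnings
            return out
        try:
            model = fit_imputation_model(data, spec)
        except InestimableModelError as err:
            notes.append(str(err))
            continue
        out = draw_imputations(model, data, m, seed)
        out.warnings = notes
        return out
    raise InestimableModelError(
        f"marker {data.marker_id}: no covariate set in {list(order)} was estimable"
    )


def single_impute(data: MarkerDataset, mode: str,
                  completed: Optional[np.ndarray] = None,
                  seed: Optional[int] = None) -> np.ndarray:
    """One completed genotype vector.

    mode='external' validates a vector completed elsewhere (e.g. by a
    phasing tool) against the observed entries; mode='best_guess' fills
    each missing entry with the highest-probability category under the
    fitted (or marginal) model; mode='random' takes one proper draw.
    """
    if mode == "external":
        if completed is None:
            raise DomainError("mode='external' requires a completed vector")
        completed = np.asarray(completed, dtype=np.int8)
        if completed.shape != data.genotypes.shape:
            raise DomainError("completed vector length does not match the dataset")
        if np.any(completed == MISSING):
            raise DomainError("external completed vector still contains missing entries")
        obs = ~data.missing_mask
        bad = np.nonzero(obs & (completed != data.genotypes))[0]
        if len(bad):
            raise DomainError(
                f"marker {data.marker_id}: external vector disagrees with "
                f"observed genotypes at samples {bad.tolist()[:20]}"
            )
        return completed.copy()
    if mode == "random":
        if seed is None:
            raise DomainError("mode='random' requires a seed")
        return impute_with_fallback(data, m=1, seed=seed).completed[0]
    if mode != "best_guess":
        raise DomainError(f"unknown single-imputation mode '{mode}'")

    out = data.genotypes.copy()
    miss = np.nonzero(data.missing_mask)[0]
    if not len(miss):
        return out
    for spec in ("flanking", "intensities", "flanking+intensities"):
        try:
            model = fit_imputation_model(data, spec)
        except InestimableModelError:
            continue
        X = _model_design_rows(model, data, miss)
        prob = model.predict_proba(X)
        out[miss] = model.categories[np.argmax(prob, axis=1)]
        return out
    g = data.genotypes[~data.missing_mask]
    cats, cnt = np.unique(g, return_counts=True)
    out[miss] = cats[np.argmax(cnt)]
    return out
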