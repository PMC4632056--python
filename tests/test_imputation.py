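"""Multinomial-logit imputation: recovery, fallbacks, determinism."""

import numpy as np
import pandas as pd
import pytest

from hwimpute import (DomainError, GenotypeCounts, InestimableModelError,
                      MarkerDataset, Mcar, SimulationConfig, derive_marker_seed,
                      draw_imputations, estimate_f, fit_imputation_model,
                      impute_with_fallback, pool_estimates, sim_marker,
                      single_impute)
from hwimpute.counts import MISSING


def make_dataset(rng, n=800, f=0.0, p_A=0.4, ld_r=0.8, rate=0.15,
                 marker_id="m1"):
    config = SimulationConfig(n=n, m_markers=1, p_A=p_A, f=f,
                              missing_mechanism=Mcar(rate), ld_r=ld_r, seed=0)
    return sim_marker(config, rng, marker_id=marker_id)


class TestFitModel:
    def test_recovers_generating_probabilities(self, rng):
        # target generated from flanks; fitted category probabilities must
        # track the empirical conditional distribution of the complete data
        ds = make_dataset(rng, n=2000, ld_r=0.8, rate=0.0)
        model = fit_imputation_model(ds, "flanking")
        X = model.design_for(ds, np.arange(ds.n_samples))[:, model._keep]
        prob = model.predict_proba(X)
        left = ds.covariates["left_flank"].to_numpy()
        right = ds.covariates["right_flank"].to_numpy()
        for l in range(3):
            sel = (left == l) & (right == l)
            if sel.sum() < 50:
                continue
            emp = np.bincount(ds.genotypes[sel], minlength=3) / sel.sum()
            np.testing.assert_allclose(prob[sel].mean(axis=0),
                                       emp[model.categories], atol=0.05)

    def test_monomorphic_response_inestimable(self, rng):
        g = np.zeros(50, dtype=np.int8)
        g[:5] = MISSING
        cov = pd.DataFrame({"left_flank": np.tile([0, 1], 25),
                            "right_flank": np.tile([0, 1], 25)})
        ds = MarkerDataset("mono", g, covariates=cov)
        with pytest.raises(InestimableModelError, match="no variation"):
            fit_imputation_model(ds, "flanking")

    def test_covariates_missing_for_target_rows_inestimable(self, rng):
        ds = make_dataset(rng, n=300, rate=0.2)
        miss = ds.missing_mask
        cov = ds.covariates.copy()
        cov.loc[miss, "left_flank"] = MISSING
        cov.loc[miss, "right_flank"] = MISSING
        ds2 = MarkerDataset("m2", ds.genotypes, covariates=cov)
        with pytest.raises(InestimableModelError, match="same"):
            fit_imputation_model(ds2, "flanking")

    def test_perfect_separation_inestimable(self):
        # flank identical to target: complete separation of the categories
        rng = np.random.default_rng(5)
        g = rng.choice([0, 1, 2], size=200).astype(np.int8)
        cov = pd.DataFrame({"left_flank": g, "right_flank": g})
        gm = g.copy()
        gm[:20] = MISSING
        ds = MarkerDataset("sep", gm, covariates=cov)
        with pytest.raises(InestimableModelError):
            fit_imputation_model(ds, "flanking")


class TestDrawImputations:
    def test_observed_entries_never_altered(self, rng):
        ds = make_dataset(rng, rate=0.2)
        imp = impute_with_fallback(ds, m=10, seed=7)
        obs = ~ds.missing_mask
        for vec in imp.completed:
            assert np.array_equal(vec[obs], ds.genotypes[obs])
            assert not np.any(vec == MISSING)

    def test_zero_missing_is_noop(self, rng):
        ds = make_dataset(rng, rate=0.0)
        model = fit_imputation_model(ds, "flanking")
        imp = draw_imputations(model, ds, m=5, seed=3)
        assert np.array_equal(imp.completed, np.tile(ds.genotypes, (5, 1)))

    def test_deterministic_given_seed(self, rng):
        ds = make_dataset(rng, rate=0.2)
        a = impute_with_fallback(ds, m=6, seed=11)
        b = impute_with_fallback(ds, m=6, seed=11)
        assert np.array_equal(a.completed, b.completed)
        assert a.model_used == b.model_used
        c = impute_with_fallback(ds, m=6, seed=12)
        assert not np.array_equal(a.completed, c.completed)

    def test_m_fifty_shape(self, rng):
        ds = make_dataset(rng, n=300, rate=0.1)
        imp = impute_with_fallback(ds, m=50, seed=1)
        assert imp.m == 50 and imp.completed.shape == (50, 300)
        assert len(imp.counts) == 50

    def test_only_observed_categories_imputed(self, rng):
        # a homozygote absent from the data can never be imputed
        g = np.array([0] * 200 + [1] * 100 + [-1] * 40, dtype=np.int8)
        rng.shuffle(g)
        ds = MarkerDataset("two_cat", g)
        imp = impute_with_fallback(ds, m=20, seed=3, order=("marginal",))
        assert set(np.unique(imp.completed)) <= {0, 1}


class TestFallbackChain:
    def test_flanking_preferred_when_estimable(self, rng):
        ds = make_dataset(rng, ld_r=0.8, rate=0.15)
        assert impute_with_fallback(ds, m=3, seed=0).model_used == "flanking"

    def test_intensities_when_flanks_share_missingness(self, rng):
        ds = make_dataset(rng, rate=0.2)
        cov = ds.covariates.copy()
        miss = ds.missing_mask
        cov.loc[miss, "left_flank"] = MISSING
        cov.loc[miss, "right_flank"] = MISSING
        ds2 = MarkerDataset("m3", ds.genotypes, covariates=cov)
        imp = impute_with_fallback(ds2, m=3, seed=0)
        assert imp.model_used == "intensities"
        assert any("same" in w for w in imp.warnings)

    def test_marginal_when_no_covariates(self, rng):
        g = make_dataset(rng, rate=0.2).genotypes
        ds = MarkerDataset("bare", g)
        imp = impute_with_fallback(ds, m=4, seed=0)
        assert imp.model_used == "marginal"
        assert not imp.inestimable_flag

    def test_monomorphic_marginal_flagged(self):
        g = np.array([0] * 90 + [-1] * 10, dtype=np.int8)
        ds = MarkerDataset("mono", g)
        imp = impute_with_fallback(ds, m=4, seed=0)
        assert imp.inestimable_flag
        assert np.all(imp.completed == 0)
        assert imp.warnings


class TestSingleImpute:
    def test_external_round_trip(self, rng):
        ds = make_dataset(rng, rate=0.1)
        vec = ds.genotypes.copy()
        vec[ds.missing_mask] = 1
        out = single_impute(ds, "external", completed=vec)
        assert np.array_equal(out, vec)

    def test_external_conflict_rejected(self, rng):
        ds = make_dataset(rng, rate=0.1)
        vec = ds.genotypes.copy()
        vec[ds.missing_mask] = 0
        obs_idx = np.nonzero(~ds.missing_mask)[0][0]
        vec[obs_idx] = (vec[obs_idx] + 1) % 3
        with pytest.raises(DomainError, match="disagrees"):
            single_impute(ds, "external", completed=vec)

    def test_best_guess_beats_marginal_baseline(self, rng):
        ds = make_dataset(rng, n=1500, ld_r=0.9, rate=0.2)
        truth = ds.true_genotypes
        miss = ds.missing_mask
        bg = single_impute(ds, "best_guess")
        acc_model = np.mean(bg[miss] == truth[miss])
        counts = ds.observed_counts()
        acc_marginal = max(counts.as_tuple()) / counts.n
        assert acc_model > acc_marginal
        assert acc_model > 0.5

    def test_random_mode_deterministic(self, rng):
        ds = make_dataset(rng, rate=0.15)
        a = single_impute(ds, "random", seed=5)
        b = single_impute(ds, "random", seed=5)
        assert np.array_equal(a, b)


class TestMiRecovery:
    def test_mi_beats_discard_at_informative_flanks(self, rng):
        # MCAR 20%, strong LD: pooled MI estimate closer to truth in RMSE
        f_true, reps = 0.1, 120
        err_mi, err_disc = [], []
        config = SimulationConfig(n=400, m_markers=1, p_A=0.35, f=f_true,
                                  missing_mechanism=Mcar(0.2), ld_r=0.85, seed=0)
        for i in range(reps):
            ds = sim_marker(config, rng, marker_id=f"r{i}")
            disc = estimate_f(ds.observed_counts()).f_hat
            imp = impute_with_fallback(ds, m=8, seed=derive_marker_seed(9, ds.marker_id))
            ests = [(estimate_f(c).f_hat, 1.0 / c.n) for c in imp.counts]
            mi = pool_estimates(ests).estimate
            err_disc.append(disc - f_true)
            err_mi.append(mi - f_true)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(err_mi) <= rmse(err_disc)
        assert abs(np.mean(err_mi)) < 0.02


class TestSeedDerivation:
    def test_stable_and_order_independent(self):
        s1 = derive_marker_seed(42, "rs123")
        assert s1 == derive_marker_seed(42, "rs123")
        assert s1 != derive_marker_seed(42, "rs124")
        assert s1 != derive_marker_seed(43, "rs123")
        assert 0 <= s1 < 2 ** 31
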