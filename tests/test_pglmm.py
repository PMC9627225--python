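"""PQL fitting of the binary phylogenetic GLMM: oracles and invariants."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import special

from phyloccur.composites import AreaStress, TraitScores
from phyloccur.io import OccurrenceMatrix
from phyloccur.pglmm import (
    MAIN_COLUMNS,
    PGLMMControl,
    PhyloBinaryGLMM,
    build_design,
)


def _scores(species, rng):
    return TraitScores(data=pd.DataFrame({
        "pc1_leaf_fruit": rng.standard_normal(len(species)),
        "pc2_flower_vs_height": rng.standard_normal(len(species)),
    }, index=species))


def _stress(areas, rng):
    s = rng.standard_normal(len(areas))
    return AreaStress(data=pd.Series(s - s.mean(), index=areas, name="stress"))


def _mem(areas, rng):
    v = rng.standard_normal(len(areas))
    v = v - v.mean()
    return pd.Series(v / np.linalg.norm(v), index=areas, name="mem")


def _toy_inputs(n=3, m=2, seed=0):
    rng = np.random.default_rng(seed)
    species = [f"s{i}" for i in range(n)]
    areas = [f"a{j}" for j in range(m)]
    occ = (rng.random((n, m)) < 0.6).astype(int)
    occ[occ.sum(axis=1) == 0, 0] = 1
    return (OccurrenceMatrix(data=pd.DataFrame(occ, index=species, columns=areas)),
            _scores(species, rng), _stress(areas, rng), _mem(areas, rng))


class TestBuildDesign:
    def test_shapes_and_interaction_products(self):
        occ, sc, st, mem = _toy_inputs(3, 2)
        d = build_design(occ, sc, st, mem)
        assert d.X.shape == (6, 9)
        np.testing.assert_allclose(
            d.X["pc1:stress"], d.X["pc1"] * d.X["stress"], atol=1e-15)
        np.testing.assert_allclose(
            d.X["pc2:mem"], d.X["pc2"] * d.X["mem"], atol=1e-15)

    def test_species_indicator_structure(self):
        occ, sc, st, mem = _toy_inputs(4, 3)
        d = build_design(occ, sc, st, mem)
        counts = np.bincount(d.species_index)
        assert (counts == 3).all()  # each Z column sums to m
        assert len(d.species_index) == 12  # one 1 per row

    def test_interaction_only_design(self):
        occ, sc, st, mem = _toy_inputs(3, 3)
        d = build_design(occ, sc, st, mem, include_main_effects=False)
        assert list(d.X.columns) == [
            "intercept", "pc1:stress", "pc2:stress", "pc1:mem", "pc2:mem"]

    def test_row_count_scales_with_species_and_areas(self):
        occ, sc, st, mem = _toy_inputs(20, 9)
        d = build_design(occ, sc, st, mem)
        assert d.n_obs == 180

    def test_nonfinite_covariate_errors(self):
        occ, sc, st, mem = _toy_inputs(3, 2)
        sc.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_design(occ, sc, st, mem)


class TestGLMLimit:
    def test_zero_variances_match_irls_logistic(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        N, n_spp = 500, 50
        X = np.column_stack([np.ones(N), rng.standard_normal((N, 3))])
        beta_true = np.array([-0.3, 0.8, -0.5, 0.2])
        y = (rng.random(N) < special.expit(X @ beta_true)).astype(float)
        spp = rng.integers(0, n_spp, N)
        fit = PhyloBinaryGLMM(y, X, spp, np.eye(n_spp)).fit(
            control=PGLMMControl(tol=1e-10, max_outer_iter=100),
            fix_sigma2_a=0.0, fix_sigma2_b=0.0)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)


class TestWaldTable:
    def _fit(self):
        rng = np.random.default_rng(0)
        N, n_spp = 200, 20
        X = np.column_stack([np.ones(N), rng.standard_normal(N)])
        y = (rng.random(N) < 0.5).astype(float)
        spp = np.repeat(np.arange(n_spp), N // n_spp)
        return PhyloBinaryGLMM(y, X, spp, np.eye(n_spp)).fit(
            fix_sigma2_a=0.0, fix_sigma2_b=0.0)

    def test_z_and_p_definitions(self):
        fit = self._fit()
        tab = fit.wald_table()
        np.testing.assert_allclose(tab["z"], tab["estimate"] / tab["std_error"])
        from scipy import stats
        np.testing.assert_allclose(
            tab["p"], 2 * stats.norm.sf(np.abs(tab["z"])), atol=1e-12)

    def test_reference_quantile(self):
        # |z| = 1.959964 corresponds to p = 0.05
        from scipy import stats
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_p_sign_symmetric_and_zero_estimate(self):
        fit = self._fit()
        flipped = fit.params.copy()
        z = np.abs(flipped / fit.bse)
        from scipy import stats
        p_pos = 2 * stats.norm.sf(z)
        p_neg = 2 * stats.norm.sf(np.abs(-flipped / fit.bse))
        np.testing.assert_allclose(p_pos, p_neg)
        assert 2 * stats.norm.sf(0.0) == pytest.approx(1.0)


class TestPredict:
    def test_zero_coefficients_give_half(self):
        occ, sc, st, mem = _toy_inputs(4, 3, seed=1)
        d = build_design(occ, sc, st, mem)
        model = PhyloBinaryGLMM.from_design(d, np.eye(4))
        fit = model.fit(fix_sigma2_a=0.0, fix_sigma2_b=0.0,
                        control=PGLMMControl(max_outer_iter=1, tol=1e30))
        fit.params[:] = 0.0
        fit.conditional_modes[:] = 0.0
        np.testing.assert_allclose(fit.predict(d), 0.5, atol=1e-12)

    def test_monotone_in_positive_coefficient(self):
        occ, sc, st, mem = _toy_inputs(10, 5, seed=2)
        d = build_design(occ, sc, st, mem)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = PhyloBinaryGLMM.from_design(d, np.eye(10)).fit(
                fix_sigma2_a=0.0, fix_sigma2_b=0.1)
        j = "pc1"
        sign = np.sign(fit.params[j]) or 1.0
        X2 = d.X.copy()
        X2[j] = X2[j] + sign  # move along the coefficient's own direction
        d2 = type(d)(y=d.y, X=X2, species_index=d.species_index,
                     species=d.species, areas=d.areas)
        assert (fit.predict(d2) >= fit.predict(d) - 1e-12).all()

    def test_dimension_mismatch_errors(self):
        occ, sc, st, mem = _toy_inputs(4, 3, seed=3)
        d = build_design(occ, sc, st, mem)
        fit = PhyloBinaryGLMM.from_design(d, np.eye(4)).fit(
            fix_sigma2_a=0.0, fix_sigma2_b=0.0)
        d5, *_ = _toy_inputs(5, 3, seed=4)
        dd = build_design(d5, _scores(d5.species, np.random.default_rng(0)),
                          st, mem)
        with pytest.raises(ValueError, match="species set"):
            fit.predict(dd)


class TestPQLInvariants:
    def _sim_fit(self, order="species"):
        rng = np.random.default_rng(8)
        n, m = 30, 6
        spp = np.repeat(np.arange(n), m)
        X = np.column_stack([np.ones(n * m), rng.standard_normal((n * m, 2))])
        A = rng.standard_normal((n, n))
        Sigma = A @ A.T
        Sigma /= np.diag(Sigma).max()
        np.fill_diagonal(Sigma, 1.0)
        b = np.linalg.cholesky(Sigma + 1e-8 * np.eye(n)) @ rng.standard_normal(n) * 0.5
        y = (rng.random(n * m) < special.expit(X @ np.array([0.2, 0.6, -0.4])
                                               + b[spp])).astype(float)
        if order == "area":
            idx = np.argsort(np.tile(np.arange(m), n), kind="stable")
            y, X, spp = y[idx], X[idx], spp[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PhyloBinaryGLMM(y, X, spp, Sigma).fit(
                control=PGLMMControl(tol=1e-8))

    def test_row_order_invariance(self):
        f1 = self._sim_fit("species")
        f2 = self._sim_fit("area")
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-6)
        assert f1.sigma2_b == pytest.approx(f2.sigma2_b, abs=1e-5)

    def test_identity_sigma_exchangeable_variances_stable(self):
        rng = np.random.default_rng(11)
        n, m = 40, 6
        spp = np.repeat(np.arange(n), m)
        X = np.column_stack([np.ones(n * m), rng.standard_normal(n * m)])
        u = rng.standard_normal(n) * 0.7
        y = (rng.random(n * m) < special.expit(X @ np.array([0.0, 0.5])
                                               + u[spp])).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = PhyloBinaryGLMM(y, X, spp, np.eye(n)).fit()
        # only the sum is identified; the fit must stay finite and bounded
        assert np.isfinite(fit.params.to_numpy()).all()
        assert 0.0 <= fit.sigma2_a <= 10.0
        assert 0.0 <= fit.sigma2_b <= 10.0

    def test_deterministic_given_inputs(self):
        f1 = self._sim_fit()
        f2 = self._sim_fit()
        pd.testing.assert_series_equal(f1.params, f2.params)
        assert f1.sigma2_a == f2.sigma2_a and f1.sigma2_b == f2.sigma2_b


class TestSignRecovery:
    def test_simulated_signs_recovered(self, small_sim):
        """Moderate-size simulation: the two nonzero coefficients keep their
        generating signs in the fitted model."""
        from phyloccur.phylo import brownian_vcv
        ds, truth = small_sim
        vcv = brownian_vcv(ds.tree, species=ds.species)
        sc = TraitScores(data=truth["trait_scores"].data.loc[ds.species])
        design = build_design(ds.occurrence, sc, truth["stress"], truth["mem"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = PhyloBinaryGLMM.from_design(design, vcv).fit()
        assert fit.params["pc1"] < 0
        assert fit.params["pc1:stress"] < 0
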