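import math

import numpy as np
import pandas as pd
import pytest

import geoblup as gb
from geoblup.kernels import KernelSpec, build_gamma
from geoblup.markers import GenotypeMatrix, distance_matrix
from geoblup.model import (
    GenomicBLUP,
    ModelSpec,
    VarianceComponents,
    fit_model,
    reml_loglik,
)
from geoblup.pedigree import Pedigree, build_omega_design

from conftest import random_genotype_matrix


def dense_reml_oracle(y, V):
    """Direct-formula REML log-likelihood via explicit inverses."""
    n = len(y)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        (n - 1) * math.log(2 * math.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(y @ P @ y)
    )


def make_data(seed, n=40, m=25, kernel=None, sg=1.0, se=1.0, mu=5.0):
    rng = np.random.default_rng(seed)
    gm = random_genotype_matrix(rng, n, m)
    if kernel is None:
        G = gm.Z @ gm.Z.T
    else:
        G = build_gamma(kernel, distance_matrix(gm)).Gamma
    w, U = np.linalg.eigh(G)
    L = U * np.sqrt(np.clip(w, 0, None))
    y = mu + np.sqrt(sg) * (L @ rng.normal(size=n)) + rng.normal(0, np.sqrt(se), n)
    return gm, pd.Series(y, index=list(gm.individual_ids))


class TestRemlLoglik:
    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(20)
        n = 18
        gm = random_genotype_matrix(rng, n, 10)
        G = gm.Z @ gm.Z.T
        y = rng.normal(2, 1.5, n)
        vc = VarianceComponents(sigma2_g=0.07, sigma2_e=1.1)
        V = 0.07 * G + 1.1 * np.eye(n)
        assert reml_loglik(y, vc, gamma=G) == pytest.approx(
            dense_reml_oracle(y, V), abs=1e-10
        )

    def test_with_fixed_R_and_omega(self):
        rng = np.random.default_rng(21)
        n = 12
        rows = [(f"i{k}", f"F{k % 3}", f"M{k % 2}") for k in range(n)]
        ped = Pedigree.from_frame(
            pd.DataFrame(rows, columns=["individual", "father", "mother"])
        )
        od = build_omega_design(ped, [r[0] for r in rows])
        G = np.eye(n)
        R = rng.uniform(0.1, 0.4, n)
        y = rng.normal(0, 1, n)
        vc = VarianceComponents(sigma2_g=0.5, sigma2_v=0.8, sigma2_f=0.3, sigma2_m=0.2, sigma2_c=0.1)
        V = (
            0.5 * G + 0.8 * np.eye(n) + np.diag(R)
            + 0.3 * od.V_f + 0.2 * od.V_m + 0.1 * od.V_c
        )
        assert reml_loglik(y, vc, gamma=G, R=R, omega_design=od) == pytest.approx(
            dense_reml_oracle(y, V), abs=1e-10
        )

    def test_iid_collapse_closed_form(self):
        """Independent model: REML variance is the n-1 sample variance."""
        rng = np.random.default_rng(22)
        y = rng.normal(3, 2, 30)
        n = len(y)
        s2 = np.var(y, ddof=1)
        closed = -0.5 * (
            (n - 1) * math.log(2 * math.pi)
            + n * math.log(s2)
            + math.log(n / s2)
            + (n - 1)
        )
        vc = VarianceComponents(sigma2_e=s2)
        assert reml_loglik(y, vc) == pytest.approx(closed, abs=1e-10)

    def test_nonpd_rejected(self):
        y = np.zeros(3)
        with pytest.raises(np.linalg.LinAlgError):
            reml_loglik(y, VarianceComponents(sigma2_g=-5.0, sigma2_e=0.1), gamma=np.eye(3))


class TestFitModel:
    def test_independent_matches_sample_variance(self, small_sim):
        _, sim = small_sim
        rng = np.random.default_rng(23)
        ids = list(sim.phenotyped_ids)
        y = pd.Series(rng.normal(10, 2, len(ids)), index=ids)
        res = GenomicBLUP(y, sim.genotypes, kernel="independent").fit()
        assert res.varcomp.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=1e-5)
        assert res.mu == pytest.approx(y.mean(), rel=1e-8)
        assert res.n_covariance_params == 1

    def test_scaling_transformation(self):
        """y -> c*y scales variances by c^2 and shifts max loglik by -(n-1) log c."""
        gm, y = make_data(24, n=35, m=20, sg=0.05, se=1.0)
        c = 3.0
        r1 = GenomicBLUP(y, gm, kernel="rr").fit()
        r2 = GenomicBLUP(c * y, gm, kernel="rr").fit()
        n = len(y)
        assert r2.varcomp.sigma2_g == pytest.approx(c**2 * r1.varcomp.sigma2_g, rel=1e-4)
        assert r2.varcomp.sigma2_e == pytest.approx(c**2 * r1.varcomp.sigma2_e, rel=1e-4)
        assert r2.llf == pytest.approx(r1.llf - (n - 1) * math.log(c), abs=1e-5)

    def test_lambda2_reported_for_rr(self):
        gm, y = make_data(25, sg=0.1, se=1.0)
        res = GenomicBLUP(y, gm, kernel="rr").fit()
        assert res.lambda2 == pytest.approx(
            res.varcomp.sigma2_e / res.varcomp.sigma2_g
        )

    def test_fixed_theta_skips_parameter_count(self):
        gm, y = make_data(26, kernel=KernelSpec("gaussian", 6.0), sg=2.0, se=1.0)
        fixed = GenomicBLUP(y, gm, kernel=KernelSpec("gaussian", 6.0)).fit()
        profiled = GenomicBLUP(y, gm, kernel="gaussian").fit()
        assert fixed.n_covariance_params == 2
        assert profiled.n_covariance_params == 3
        # profiling can only improve the maximized log-likelihood
        assert profiled.llf >= fixed.llf - 1e-6

    def test_nested_models_loglik_monotone(self):
        gm, y = make_data(27, n=45, m=20, sg=0.08, se=1.0)
        rng = np.random.default_rng(27)
        rows = [(i, f"F{k % 4}", f"M{k % 5}") for k, i in enumerate(gm.individual_ids)]
        ped = Pedigree.from_frame(
            pd.DataFrame(rows, columns=["individual", "father", "mother"])
        )
        base = GenomicBLUP(y, gm, kernel="rr").fit()
        extended = GenomicBLUP(y, gm, kernel="rr", pedigree=ped).fit()
        assert extended.llf >= base.llf - 1e-6
        assert extended.n_covariance_params == 5

    def test_fixed_residual_mode(self, small_sim, small_stage1):
        _, sim = small_sim
        s1 = small_stage1
        res = GenomicBLUP(
            s1.predictions,
            sim.genotypes,
            kernel="rr",
            residual="fixed",
            error_variances=s1.error_variances,
        ).fit()
        assert res.varcomp.sigma2_v is not None
        assert res.varcomp.sigma2_e is None
        assert res.model.spec.residual_mode == "fixed"

    def test_fit_model_wrapper(self, small_sim, small_stage1):
        _, sim = small_sim
        s1 = small_stage1
        res = fit_model(
            ModelSpec(KernelSpec("rr")), s1.predictions, sim.genotypes,
            error_variances=s1.error_variances,
        )
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_covariance_params)

    def test_aic_formula_example(self):
        class Dummy:
            llf = -100.0
            n_covariance_params = 2
            aic = property(lambda self: -2 * self.llf + 2 * self.n_covariance_params)

        assert Dummy().aic == 204.0


class TestBlup:
    def test_ridge_normal_equations_identity(self):
        """Z u_ridge = g_blup at lambda^2 = sigma2_e/sigma2_g (rr kernel)."""
        gm, y = make_data(28, n=50, m=30, sg=0.05, se=1.0)
        res = GenomicBLUP(y, gm, kernel="rr").fit()
        u = res.ridge_effects()
        assert np.max(np.abs(gm.Z @ u - res.genetic_blup)) < 1e-8

    def test_identical_marker_vector_same_genetic_blup(self):
        gm, y = make_data(29, n=30, m=15, sg=0.1, se=0.5)
        res = GenomicBLUP(y, gm, kernel="rr").fit()
        clone = GenotypeMatrix(gm.Z[[4]], ("clone",), gm.marker_ids)
        pred = res.predict(genotypes=clone)
        assert pred["clone"] - res.mu == pytest.approx(res.genetic_blup[4], abs=1e-10)

    def test_vanishing_genetic_variance_shrinks_gebv_to_mu(self):
        """Pure-noise data: sigma2_g -> 0 and every GEBV -> mu."""
        rng = np.random.default_rng(30)
        gm = random_genotype_matrix(rng, 40, 10)
        y = pd.Series(rng.normal(7, 1, 40), index=list(gm.individual_ids))
        res = GenomicBLUP(y, gm, kernel="rr").fit()
        shrink = np.abs(res.gebv - res.mu).max()
        assert shrink < 0.25 * float(np.abs(y - y.mean()).max())
        if res.varcomp.sigma2_g == 0:
            assert shrink == 0.0

    def test_gebv_table_flags(self, small_sim, small_stage1):
        _, sim = small_sim
        res = GenomicBLUP(small_stage1.predictions, sim.genotypes, kernel="rr").fit()
        table = res.gebv_table()
        assert set(table.columns) == {"gebv", "phenotyped"}
        assert table["phenotyped"].sum() == len(small_stage1.predictions)
        assert len(table) == sim.genotypes.n_individuals

    def test_polygenic_blup_completes_fitted_values(self, small_sim, small_stage1):
        _, sim = small_sim
        res = GenomicBLUP(small_stage1.predictions, sim.genotypes, kernel="rr").fit()
        fitted = res.mu + res.genetic_blup + res.polygenic_blup
        assert np.allclose(fitted, res.fittedvalues.to_numpy())


class TestSummary:
    def test_summary_mentions_key_quantities(self, small_sim, small_stage1):
        _, sim = small_sim
        res = GenomicBLUP(small_stage1.predictions, sim.genotypes, kernel="rr").fit()
        text = res.summary()
        for token in ("sigma2_g", "sigma2_e", "AIC", "REML", "lambda^2"):
            assert token in text

    def test_to_dict_serializable(self, small_sim, small_stage1):
        import json

        _, sim = small_sim
        res = GenomicBLUP(small_stage1.predictions, sim.genotypes, kernel="gaussian").fit()
        blob = json.dumps(res.to_dict())
        assert "theta" in blob


class TestValidation:
    def test_y_must_be_series(self, small_sim):
        _, sim = small_sim
        with pytest.raises(TypeError):
            GenomicBLUP(np.zeros(5), sim.genotypes)

    def test_fixed_mode_requires_error_variances(self, small_sim, small_stage1):
        _, sim = small_sim
        with pytest.raises(ValueError, match="error_variances"):
            GenomicBLUP(small_stage1.predictions, sim.genotypes, residual="fixed")

    def test_missing_genotype_rejected(self, small_sim):
        _, sim = small_sim
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=["nope1", "nope2", "nope3", "nope4"])
        with pytest.raises(KeyError):
            GenomicBLUP(y, sim.genotypes, kernel="rr")
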