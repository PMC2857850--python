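import numpy as np
import pytest
from hypothesis import given, strategies as st

from geoblup.kernels import (
    SPATIAL_KERNELS,
    CorrelationMatrix,
    KernelSpec,
    build_gamma,
    build_rr_gamma,
    kernel_value,
    stabilize,
)
from geoblup.markers import DistanceMatrix, GenotypeMatrix, distance_matrix

from conftest import random_genotype_matrix


def dmat(n, seed=0, scale=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, scale, size=(n, 4))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(D, tuple(f"i{k}" for k in range(n)))


class TestKernelValue:
    def test_gaussian_at_zero(self):
        assert kernel_value("gaussian", 0.0, 5.0) == 1.0

    def test_gaussian_at_theta(self):
        assert kernel_value("gaussian", 2.5, 2.5) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_exponential_at_theta(self):
        assert kernel_value("exponential", 3.0, 3.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_spherical_truncates_at_range(self):
        assert kernel_value("spherical", 4.0, 4.0) == 0.0
        assert kernel_value("spherical", 5.0, 4.0) == 0.0

    def test_linear_truncates(self):
        assert kernel_value("linear", 2.0, 0.5) == 0.0
        assert kernel_value("linear", 1.0, 0.5) == pytest.approx(0.5)

    def test_quadratic_form(self):
        assert kernel_value("quadratic", 2.0, 0.1) == pytest.approx(1 - 0.1 * 4)

    def test_power_form(self):
        assert kernel_value("power", 3.0, 0.5) == pytest.approx(0.125)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            kernel_value("gaussian", 1.0, -1.0)
        with pytest.raises(ValueError):
            kernel_value("power", 1.0, 1.5)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            kernel_value("matern", 1.0, 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_value("gaussian", -0.5, 1.0)

    @pytest.mark.parametrize("name", SPATIAL_KERNELS)
    def test_unit_at_zero_and_monotone(self, name):
        theta = 0.7 if name == "power" else 3.0
        d = np.linspace(0, 10, 200)
        f = np.asarray(kernel_value(name, d, theta))
        assert f[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(f) <= 1e-12)

    @given(
        st.sampled_from(SPATIAL_KERNELS),
        st.floats(0.0, 20.0),
        st.floats(0.0, 20.0),
        st.floats(0.05, 0.95),
    )
    def test_monotonicity_property(self, name, d1, d2, u):
        theta = u if name == "power" else 0.5 + 10 * u
        lo, hi = sorted((d1, d2))
        assert kernel_value(name, lo, theta) >= kernel_value(name, hi, theta) - 1e-12


class TestBuildGamma:
    def test_independent_gives_identity(self):
        D = dmat(6)
        G = build_gamma(KernelSpec("independent"), D).Gamma
        assert np.array_equal(G, np.eye(6))

    def test_exponential_vanishes_at_huge_distance(self):
        D = DistanceMatrix(1e6 * (1 - np.eye(4)), tuple("abcd"))
        G = build_gamma(KernelSpec("exponential", 2.0), D).Gamma
        assert np.allclose(G, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("name", SPATIAL_KERNELS)
    def test_matches_scalar_loop_oracle(self, name):
        theta = 0.6 if name == "power" else 4.0
        D = dmat(7, seed=3)
        G = build_gamma(KernelSpec(name, theta), D).Gamma
        for i in range(7):
            for j in range(7):
                expect = 1.0 if i == j else kernel_value(name, D.D[i, j], theta)
                assert G[i, j] == pytest.approx(float(expect), abs=1e-12)

    def test_rr_requires_z(self):
        with pytest.raises(ValueError):
            build_gamma(KernelSpec("rr"), dmat(3))


class TestRRGamma:
    def test_single_individual(self):
        gm = GenotypeMatrix(np.array([[1.0, -1.0, 0.0]]), ("a",), ("m1", "m2", "m3"))
        assert build_rr_gamma(gm).Gamma.tolist() == [[2.0]]

    def test_identical_rows_equal_entries(self):
        Z = np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0]])
        G = build_rr_gamma(GenotypeMatrix(Z, ("a", "b"), ("m1", "m2", "m3"))).Gamma
        assert G[0, 0] == G[0, 1] == G[1, 1]

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(7)
        gm = random_genotype_matrix(rng, 15, 9)
        w = np.linalg.eigvalsh(build_rr_gamma(gm).Gamma)
        assert w.min() >= -1e-9


class TestStabilize:
    def test_psd_input_unchanged(self):
        G = CorrelationMatrix(np.eye(3), ("a", "b", "c"), KernelSpec("independent"))
        out, report = stabilize(G)
        assert out is G
        assert not report.adjusted

    def test_indefinite_clipped(self):
        G = CorrelationMatrix(
            np.array([[1.0, 1.5], [1.5, 1.0]]), ("a", "b"), KernelSpec("rr")
        )
        out, report = stabilize(G)
        assert report.adjusted
        assert np.linalg.eigvalsh(out.Gamma).min() >= -1e-9

    def test_jitter_policy(self):
        G = CorrelationMatrix(
            np.array([[1.0, 1.5], [1.5, 1.0]]), ("a", "b"), KernelSpec("rr")
        )
        out, report = stabilize(G, policy="jitter")
        assert report.adjusted
        assert np.linalg.eigvalsh(out.Gamma).min() >= -1e-9
        # jitter preserves off-diagonals
        assert out.Gamma[0, 1] == pytest.approx(1.5)


class TestStructuralIdentities:
    def test_gaussian_approaches_quadratic_at_rate_theta4(self):
        """sup|exp(-d^2/th^2) - (1 - d^2/th^2)| decays like theta^-4."""
        D = dmat(8, seed=5)
        gaps = []
        thetas = [50.0, 100.0, 200.0]
        for th in thetas:
            G = build_gamma(KernelSpec("gaussian", th), D).Gamma
            Q = 1 - D.D**2 / th**2
            np.fill_diagonal(Q, 1.0)
            gaps.append(np.max(np.abs(G - Q)))
        assert gaps[2] < gaps[1] < gaps[0]
        # halving 1/theta should shrink the gap ~16x
        assert gaps[1] / gaps[0] == pytest.approx(1 / 16, rel=0.2)
        assert gaps[2] / gaps[1] == pytest.approx(1 / 16, rel=0.2)

    def test_rr_equals_m11_minus_half_D2_on_heterozygote_free_Z(self):
        rng = np.random.default_rng(8)
        n, m = 12, 20
        Z = np.where(rng.random((n, m)) < 0.5, 1.0, -1.0)
        gm = GenotypeMatrix(Z, tuple(f"i{k}" for k in range(n)),
                            tuple(f"m{k}" for k in range(m)))
        D = distance_matrix(gm).D
        expect = m * np.ones((n, n)) - D**2 / 2
        assert np.allclose(build_rr_gamma(gm).Gamma, expect, atol=1e-9)


def test_kernelspec_validation():
    with pytest.raises(ValueError):
        KernelSpec("rr", theta=1.0)
    with pytest.raises(ValueError):
        KernelSpec("gaussian", theta=-2.0)
    with pytest.raises(ValueError):
        KernelSpec("unknown")
    assert KernelSpec("gaussian", 3.0).is_spatial
    assert not KernelSpec("rr").is_spatial
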