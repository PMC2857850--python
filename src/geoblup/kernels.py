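"""Genotypic covariance kernels.

The genetic covariance of marker-explained effects is var(g) = sigma2_g * Gamma,
where Gamma is either ``Z Z'`` (the ridge-regression / GBLUP form) or a
geostatistical correlation matrix ``{f(d_ii')}`` built from the Euclidean
distances between marker-code vectors.  The correlation functions are the
classical spatial-statistics structures:

========  ==========================================================
name      f(d)
========  ==========================================================
linear      (1 - theta*d)           for theta*d   <= 1, else 0
quadratic   (1 - theta*d^2)         for theta*d^2 <= 1, else 0
power       theta**d                with theta in (0, 1)
exponential exp(-d / theta)
gaussian    exp(-d^2 / theta^2)
spherical   1 - 1.5(d/theta) + 0.5(d/theta)^3   for d <= theta, else 0
========  ==========================================================

All spatial kernels satisfy f(0) = 1 and are monotonically non-increasing
in d.  ``independent`` denotes the model in which the marker term is
omitted (Gamma = I).  Note the quadratic kernel reproduces the ridge
kernel up to scale on heterozygote-free data: if every entry of Z is +-1
then Z Z' = m*11' - D^2/2, so Gamma_quad(theta=1/(2m)) = Z Z'/m wherever
the truncation is inactive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markers import DistanceMatrix, GenotypeMatrix

__all__ = [
    "SPATIAL_KERNELS",
    "KERNEL_NAMES",
    "KernelSpec",
    "CorrelationMatrix",
    "StabilizationReport",
    "kernel_value",
    "build_gamma",
    "build_rr_gamma",
    "stabilize",
]

KERNEL_NAMES = (
    "independent",
    "rr",
    "linear",
    "quadratic",
    "power",
    "exponential",
    "gaussian",
    "spherical",
)
#: kernels parameterized by a range/decay parameter theta
SPATIAL_KERNELS = ("linear", "quadratic", "power", "exponential", "gaussian", "spherical")


@dataclass(frozen=True)
class KernelSpec:
    """A named genotypic covariance model with optional range parameter."""

    name: str
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.name in ("independent", "rr"):
            if self.theta is not None:
                raise ValueError(f"kernel {self.name!r} takes no theta")
        elif self.theta is not None:
            _validate_theta(self.name, self.theta)

    @property
    def is_spatial(self) -> bool:
        return self.name in SPATIAL_KERNELS


def _validate_theta(name: str, theta: float) -> None:
    if not np.isfinite(theta) or theta <= 0:
        raise ValueError(f"theta must be strictly positive, got {theta}")
    if name == "power" and not theta < 1:
        raise ValueError(f"power kernel requires theta in (0, 1), got {theta}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric individuals x individuals genotypic covariance structure."""

    Gamma: np.ndarray
    ids: tuple[str, ...]
    spec: KernelSpec


@dataclass(frozen=True)
class StabilizationReport:
    """What :func:`stabilize` did to make Gamma usable in a PD covariance."""

    policy: str
    min_eigenvalue_before: float
    min_eigenvalue_after: float
    adjusted: bool


def kernel_value(name: str, d, theta: float | None = None):
    """Evaluate the correlation function f(d) of a spatial kernel.

    Vectorised over ``d``; ``d`` must be non-negative.
    """
    if name not in SPATIAL_KERNELS:
        raise ValueError(f"{name!r} is not a spatial kernel; choose from {SPATIAL_KERNELS}")
    if theta is None:
        raise ValueError(f"kernel {name!r} requires theta")
    _validate_theta(name, theta)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if name == "linear":
        return np.where(theta * d <= 1.0, 1.0 - theta * d, 0.0)
    if name == "quadratic":
        return np.where(theta * d**2 <= 1.0, 1.0 - theta * d**2, 0.0)
    if name == "power":
        return theta**d
    if name == "exponential":
        return np.exp(-d / theta)
    if name == "gaussian":
        return np.exp(-(d**2) / theta**2)
    # spherical
    r = d / theta
    return np.where(r <= 1.0, 1.0 - 1.5 * r + 0.5 * r**3, 0.0)


def build_gamma(spec: KernelSpec, distances: DistanceMatrix) -> CorrelationMatrix:
    """Elementwise Gamma = {f(d_ii')}; the independent model gives the identity."""
    n = len(distances.ids)
    if spec.name == "independent":
        return CorrelationMatrix(np.eye(n), distances.ids, spec)
    if spec.name == "rr":
        raise ValueError("rr kernel is built from Z with build_rr_gamma, not from distances")
    G = kernel_value(spec.name, distances.D, spec.theta)
    G = np.asarray(G, dtype=float)
    np.fill_diagonal(G, 1.0)
    return CorrelationMatrix(G, distances.ids, spec)


def build_rr_gamma(genotypes: GenotypeMatrix) -> CorrelationMatrix:
    """Ridge-regression covariance structure Gamma = Z Z' (positive semidefinite)."""
    Z = genotypes.Z
    if not np.all(np.isfinite(Z)):
        raise ValueError("genotype matrix contains non-finite entries")
    G = Z @ Z.T
    G = (G + G.T) / 2.0
    return CorrelationMatrix(G, tuple(genotypes.individual_ids), KernelSpec("rr"))


def stabilize(
    gamma: CorrelationMatrix,
    policy: str = "clip",
    tol: float = 1e-8,
) -> tuple[CorrelationMatrix, StabilizationReport]:
    """Make Gamma positive semidefinite (linear/quadratic/spherical need not be).

    ``clip`` projects negative eigenvalues to 0; ``jitter`` adds the smallest
    uniform diagonal shift.  PSD inputs pass through unchanged.
    """
    if policy not in ("clip", "jitter"):
        raise ValueError(f"unknown stabilization policy {policy!r}")
    G = np.asarray(gamma.Gamma, dtype=float)
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("Gamma must be symmetric")
    scale = max(1.0, float(np.max(np.abs(np.diag(G)))))
    w = np.linalg.eigvalsh(G)
    min_before = float(w[0])
    if min_before >= -tol * scale:
        report = StabilizationReport(policy, min_before, min_before, adjusted=False)
        return gamma, report
    if policy == "jitter":
        G2 = G + (-min_before) * np.eye(G.shape[0])
    else:
        w_full, U = np.linalg.eigh(G)
        G2 = (U * np.clip(w_full, 0.0, None)) @ U.T
        G2 = (G2 + G2.T) / 2.0
    min_after = float(np.linalg.eigvalsh(G2)[0])
    report = StabilizationReport(policy, min_before, min_after, adjusted=True)
    return CorrelationMatrix(G2, gamma.ids, gamma.spec), report
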