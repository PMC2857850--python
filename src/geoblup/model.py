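"""REML mixed-model engine for genome-wide prediction.

The observation model is

    y_i = mu + g_i + v_i + e_i

where y_i is the stage-1 extrapolated trait of individual i, mu an
intercept (the only fixed effect), g_i the marker-explained genetic
effect with var(g) = sigma2_g * Gamma, v_i an independent polygenic
effect with var(v) = sigma2_v * I, and e_i a residual.  Two residual
modes are supported:

``pooled``
    e is pooled with v into a single identity-variance component (they
    both multiply I and are not separately identifiable); the estimate is
    reported as the residual variance sigma2_e.
``fixed``
    var(e_i) is fixed at the known within-individual error variances from
    stage 1 (the squared prediction standard errors) and the free
    identity component is the polygenic variance sigma2_v.

An extended model adds father/mother/cross variance components through
the indicator structure Omega = sigma2_f*V_f + sigma2_m*V_m + sigma2_c*V_c.

Variance components are estimated by REML.  The log-likelihood is

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1 X| + y'Py ]

with P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1, maximised over the
components under non-negativity constraints; a kernel range parameter
theta is profiled by an outer one-dimensional search (log-spaced grid
refined by bounded minimisation).  A component whose estimate is
negligible is subjected to an explicit zero test against the profiled
likelihood and reported as an exact boundary zero.

GEBVs (genome-wide estimated breeding values) are BLUPs of mu + g_i
(plus predicted father/mother/cross effects when those components are in
the model with positive variance).  For unphenotyped individuals the
conditional-expectation form applies: mu + sigma2_g * Gamma_{new,obs}
V^-1 (y - 1*mu), with the cross-covariance block built from cross
distances (spatial kernels) or Z_new Z_obs' (ridge regression).  Under
the ridge model Gamma = ZZ' this BLUP coincides with the ridge
marker-effect solution u = (Z'Z + lambda^2 I)^-1 Z'(y - 1*mu) at
lambda^2 = sigma2_e / sigma2_g, via Z u = g_hat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize, minimize_scalar

from .kernels import (
    CorrelationMatrix,
    KernelSpec,
    StabilizationReport,
    build_gamma,
    build_rr_gamma,
    kernel_value,
    stabilize,
)
from .markers import DistanceMatrix, GenotypeMatrix, cross_distance, distance_matrix
from .pedigree import OmegaDesign, Pedigree, build_omega_design

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "GenomicBLUP",
    "GenomicBLUPResults",
    "reml_loglik",
    "fit_model",
    "blup_gebv",
    "aic",
]

_ZERO_SNAP_REL = 1e-6     # relative size below which a component faces the zero test
_ZERO_TEST_LL = 1e-7      # max log-likelihood loss accepted when pinning to 0
_IDENTITY_FLOOR = 1e-10   # relative floor keeping V positive definite


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated (or supplied) covariance parameters; None = absent from the model."""

    sigma2_g: float | None = None
    sigma2_e: float | None = None
    sigma2_v: float | None = None
    theta: float | None = None
    sigma2_f: float | None = None
    sigma2_m: float | None = None
    sigma2_c: float | None = None

    @property
    def identity_variance(self) -> float:
        """Total coefficient of I in V (polygenic and/or pooled residual)."""
        return (self.sigma2_e or 0.0) + (self.sigma2_v or 0.0)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sigma2_g",
                "sigma2_e",
                "sigma2_v",
                "theta",
                "sigma2_f",
                "sigma2_m",
                "sigma2_c",
            )
            if getattr(self, k) is not None
        }


@dataclass(frozen=True)
class ModelSpec:
    """A model to fit: kernel, residual handling, pedigree handling."""

    kernel: KernelSpec
    residual_mode: str = "pooled"  # or "fixed"
    pedigree_mode: str = "off"     # or "on"

    def __post_init__(self) -> None:
        if self.residual_mode not in ("pooled", "fixed"):
            raise ValueError("residual_mode must be 'pooled' or 'fixed'")
        if self.pedigree_mode not in ("off", "on"):
            raise ValueError("pedigree_mode must be 'off' or 'on'")

    @property
    def label(self) -> str:
        parts = [self.kernel.name]
        if self.residual_mode == "fixed":
            parts.append("fixed-resid")
        if self.pedigree_mode == "on":
            parts.append("pedigree")
        return "+".join(parts)


def _reml_from_V(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """REML log-likelihood pieces for a given marginal covariance V.

    Returns (loglik, beta_hat, Vinv_resid, cho) where Vinv_resid =
    V^-1 (y - X beta_hat).
    """
    n, p = X.shape
    cho = sla.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ViX = sla.cho_solve(cho, X, check_finite=False)
    Viy = sla.cho_solve(cho, y, check_finite=False)
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ beta
    quad = float(y @ Py)
    ll = -0.5 * ((n - p) * math.log(2.0 * math.pi) + logdetV + logdetX + quad)
    return ll, beta, Py, cho


def reml_loglik(
    y: np.ndarray,
    vc: VarianceComponents,
    gamma: np.ndarray | None = None,
    R: np.ndarray | None = None,
    omega_design: OmegaDesign | None = None,
    X: np.ndarray | None = None,
) -> float:
    """REML log-likelihood at the given variance components.

    Builds V = sigma2_g*Gamma + (sigma2_e + sigma2_v)*I + diag(R) + Omega
    and evaluates -1/2[(n-p) log 2pi + log|V| + log|X'V^-1X| + y'Py].
    ``R`` holds fixed known per-individual error variances (or None).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    V = np.zeros((n, n))
    if vc.sigma2_g is not None:
        if gamma is None:
            raise ValueError("sigma2_g given but no Gamma supplied")
        V += vc.sigma2_g * gamma
    ident = vc.identity_variance
    if ident:
        V += ident * np.eye(n)
    if R is not None:
        V += np.diag(np.asarray(R, dtype=float))
    if omega_design is not None:
        for s2, M in (
            (vc.sigma2_f, omega_design.V_f),
            (vc.sigma2_m, omega_design.V_m),
            (vc.sigma2_c, omega_design.V_c),
        ):
            if s2:
                V += s2 * M
    try:
        ll, *_ = _reml_from_V(y, X, V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"marginal covariance not positive definite at {vc.as_dict()}"
        ) from exc
    return ll


class _ComponentProblem:
    """Inner REML problem: maximise over non-negative variance multipliers.

    V(x) = R0 + sum_j x_j * C_j.  Components are preconditioned by their
    mean diagonal and the data variance so the optimizer works on O(1)
    numbers.
    """

    def __init__(self, y, X, comps: list[tuple[str, np.ndarray]], R0: np.ndarray | None):
        self.y = y
        self.X = X
        self.names = [c[0] for c in comps]
        self.mats = [np.asarray(c[1], dtype=float) for c in comps]
        self.R0 = R0
        self.n = len(y)
        self.scale = float(np.var(y, ddof=1)) or 1.0
        self.diag_scale = [max(float(np.mean(np.diag(M))), 1e-12) for M in self.mats]

    def _V(self, u: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n)) if self.R0 is None else np.diag(self.R0).astype(float)
        for uj, M, dj in zip(u, self.mats, self.diag_scale):
            if uj:
                V += (uj * self.scale / dj) * M
        return V

    def variances(self, u: np.ndarray) -> dict:
        return {
            name: float(uj * self.scale / dj)
            for name, uj, dj in zip(self.names, u, self.diag_scale)
        }

    def loglik(self, u: np.ndarray) -> float:
        try:
            ll, *_ = _reml_from_V(self.y, self.X, self._V(u))
        except np.linalg.LinAlgError:
            return -np.inf
        return ll

    def _negll_grad(self, u: np.ndarray):
        V = self._V(u)
        try:
            ll, beta, Py, cho = _reml_from_V(self.y, self.X, V)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(u)
        Vi = sla.cho_solve(cho, np.eye(self.n), check_finite=False)
        ViX = Vi @ self.X
        XtViX_inv = np.linalg.inv(self.X.T @ ViX)
        P = Vi - ViX @ XtViX_inv @ ViX.T
        grad = np.empty_like(u)
        for j, (M, dj) in enumerate(zip(self.mats, self.diag_scale)):
            dV = self.scale / dj
            tr_PM = float(np.sum(P * M)) * dV
            quad = float(Py @ (M @ Py)) * dV
            grad[j] = -0.5 * (tr_PM - quad)  # d(-ll)/du_j = +0.5(tr - quad)... sign below
        # dl/du_j = -1/2 (tr(P dV) - y'P dV P y); neg-ll gradient is its negative
        return -ll, -grad

    def solve(self, fixed_zero: set[int] = frozenset(), x0: np.ndarray | None = None,
              floor_idx: set[int] = frozenset()):
        k = len(self.mats)
        bounds = []
        for j in range(k):
            if j in fixed_zero:
                bounds.append((0.0, 0.0))
            elif j in floor_idx:
                bounds.append((_IDENTITY_FLOOR, None))
            else:
                bounds.append((0.0, None))
        starts = []
        if x0 is not None:
            starts.append(np.clip(x0, [b[0] for b in bounds], None))
        eq = np.full(k, 1.0 / k)
        starts.append(eq)
        if k > 1:
            heavy0 = np.full(k, 0.2 / max(k - 1, 1))
            heavy0[0] = 0.8
            starts.append(heavy0)
            heavy_last = np.full(k, 0.2 / max(k - 1, 1))
            heavy_last[-1] = 0.8
            starts.append(heavy_last)
        best = None
        for s in starts:
            s = np.clip(s, [b[0] for b in bounds], [b[1] if b[1] is not None else np.inf for b in bounds])
            res = minimize(
                self._negll_grad,
                s,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self, x0: np.ndarray | None = None, floor_idx: set[int] = frozenset()):
        """Solve, then apply the explicit zero test to negligible components."""
        best = self.solve(x0=x0, floor_idx=floor_idx)
        u = np.asarray(best.x, dtype=float)
        ll = -float(best.fun)
        fixed: set[int] = set()
        changed = True
        while changed:
            changed = False
            tiny = [
                j
                for j in range(len(u))
                if j not in fixed and j not in floor_idx and 0.0 < u[j] < _ZERO_SNAP_REL
            ]
            if not tiny:
                break
            j = min(tiny, key=lambda j: u[j])
            trial = self.solve(fixed_zero=fixed | {j}, x0=u, floor_idx=floor_idx)
            if -trial.fun >= ll - _ZERO_TEST_LL:
                fixed.add(j)
                u = np.asarray(trial.x, dtype=float)
                ll = max(ll, -float(trial.fun))
                changed = True
        u[list(fixed)] = 0.0
        boundary = [self.names[j] for j in range(len(u)) if u[j] == 0.0]
        return u, ll, bool(best.success), boundary


class _TwoComponentREML:
    """Fast inner REML for V = sigma2_g * Gamma + sigma2_I * I (no fixed R, no Omega).

    One eigendecomposition Gamma = U diag(w) U' reduces every evaluation to
    O(n).  The total variance s = sigma2_g + sigma2_I is profiled out in
    closed form, leaving a one-dimensional search over the variance ratio
    h = sigma2_g / s, performed on the logit scale so that ridge solutions
    with sigma2_g -> infinity at fixed sigma2_I (h -> 1 with s diverging)
    are resolved as well as the h = 0 boundary (no genetic variance).
    Produces exactly the same REML log-likelihood as the dense path.
    """

    _TMAX = 34.0  # |logit(h)| cap: 1 - h down to ~2e-15

    def __init__(self, y, X, gamma):
        self.n, self.p = X.shape
        w, U = np.linalg.eigh(gamma)
        self.w = np.clip(w, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X  # p = 1 in this package
        self.scale = float(np.var(y, ddof=1)) or 1.0
        self._const = (self.n - self.p) * math.log(2 * math.pi)

    def _profile(self, h: float):
        """Profiled log-likelihood and the profiled scale s at variance ratio h."""
        v = h * self.w + (1.0 - h)
        if np.any(v <= 0.0):
            return -np.inf, np.nan
        x = self.Xt[:, 0]
        a = float(np.sum(x * x / v))
        if a <= 0:
            return -np.inf, np.nan
        b = float(np.sum(x * self.yt / v))
        c = float(np.sum(self.yt * self.yt / v))
        quad = c - b * b / a
        if quad <= 0:
            return -np.inf, np.nan
        s = quad / (self.n - self.p)
        ll = -0.5 * (
            self._const
            + (self.n - self.p) * (1.0 + math.log(s))
            + float(np.sum(np.log(v)))
            + math.log(a)
        )
        return ll, s

    def fit(self, x0=None):
        tgrid = np.linspace(-self._TMAX, self._TMAX, 35)
        lls = np.array([self._profile(1.0 / (1.0 + math.exp(-t)))[0] for t in tgrid])
        j = int(np.argmax(lls))
        lo = tgrid[max(j - 1, 0)]
        hi = tgrid[min(j + 1, len(tgrid) - 1)]
        opt = minimize_scalar(
            lambda t: -self._profile(1.0 / (1.0 + math.exp(-t)))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        h_best = 1.0 / (1.0 + math.exp(-float(opt.x)))
        ll_best = -float(opt.fun)

        # explicit boundary candidates (exact zeros beat interior ties)
        ll0, s0 = self._profile(0.0)
        ll1, s1 = self._profile(1.0)
        if ll0 >= ll_best - _ZERO_TEST_LL:
            h_best, ll_best = 0.0, max(ll_best, ll0)
        elif ll1 >= ll_best - _ZERO_TEST_LL and np.isfinite(ll1):
            h_best, ll_best = 1.0, max(ll_best, ll1)

        ll, s = self._profile(h_best)
        boundary = []
        if h_best == 0.0:
            boundary.append("sigma2_g")
        if h_best == 1.0:
            boundary.append("sigma2_I")
        variances = {
            "sigma2_g": float(s * h_best),
            "sigma2_I": float(s * (1.0 - h_best)),
        }
        return variances, float(ll), True, boundary, h_best


class GenomicBLUP:
    """Mixed model for genome-wide prediction of breeding values.

    Parameters
    ----------
    y
        Stage-1 extrapolated trait values, a :class:`pandas.Series`
        indexed by individual id (the phenotyped/training set).
    genotypes
        :class:`~geoblup.markers.GenotypeMatrix` covering at least the
        training individuals (and any individuals to predict later).
    kernel
        Kernel name or :class:`~geoblup.kernels.KernelSpec`.  A spec with
        ``theta`` set fixes the range parameter; otherwise spatial kernels
        profile theta by REML.
    residual
        ``"pooled"`` (residual pooled with the polygenic identity
        component) or ``"fixed"`` (per-individual error variances fixed
        at ``error_variances``).
    error_variances
        Known within-individual error variances (stage-1 se^2), required
        for ``residual="fixed"``.
    pedigree
        Optional :class:`~geoblup.pedigree.Pedigree` activating the
        father/mother/cross variance components.
    """

    def __init__(
        self,
        y: pd.Series,
        genotypes: GenotypeMatrix,
        kernel: str | KernelSpec = "rr",
        *,
        residual: str = "pooled",
        error_variances: pd.Series | None = None,
        pedigree: Pedigree | None = None,
        stabilization: str = "clip",
    ):
        if not isinstance(y, pd.Series):
            raise TypeError("y must be a pandas Series indexed by individual id")
        self.ids: tuple[str, ...] = tuple(str(i) for i in y.index)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in y")
        self.y = y.to_numpy(dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trait values")
        self.genotypes = genotypes
        self.kernel = KernelSpec(kernel) if isinstance(kernel, str) else kernel
        self.spec = ModelSpec(
            self.kernel,
            residual_mode=residual,
            pedigree_mode="on" if pedigree is not None else "off",
        )
        self.pedigree = pedigree
        self.stabilization = stabilization
        self.X = np.ones((len(self.y), 1))
        self.n = len(self.y)

        if residual == "fixed":
            if error_variances is None:
                raise ValueError("residual='fixed' requires error_variances")
            ev = error_variances.reindex(list(self.ids))
            if ev.isna().any():
                missing = list(ev.index[ev.isna()])[:5]
                raise ValueError(f"missing error variances for {missing}")
            R0 = ev.to_numpy(dtype=float)
            if np.any(R0 < 0):
                raise ValueError("error variances must be non-negative")
            floor = _IDENTITY_FLOOR * (float(np.var(self.y, ddof=1)) or 1.0)
            self.R0 = np.maximum(R0, floor)
        else:
            self.R0 = None

        self.Z_obs = genotypes.subset(self.ids) if self.kernel.name != "independent" else None
        self._D_obs = distance_matrix(self.Z_obs) if self.kernel.is_spatial else None
        self.omega_design = (
            build_omega_design(pedigree, self.ids) if pedigree is not None else None
        )
        self._stab_report: StabilizationReport | None = None

    # ------------------------------------------------------------------ gamma
    def gamma(self, theta: float | None = None) -> np.ndarray | None:
        """Stabilized Gamma for the training set (None for the independent model)."""
        if self.kernel.name == "independent":
            return None
        if self.kernel.name == "rr":
            cm = build_rr_gamma(self.Z_obs)
        else:
            th = theta if theta is not None else self.kernel.theta
            if th is None:
                raise ValueError("spatial kernel needs theta")
            cm = build_gamma(KernelSpec(self.kernel.name, th), self._D_obs)
        cm, report = stabilize(cm, policy=self.stabilization)
        self._stab_report = report
        return cm.Gamma

    # ----------------------------------------------------------- theta search
    def _range_to_theta(self, r: float) -> float:
        name = self.kernel.name
        if name == "linear":
            return 1.0 / r
        if name == "quadratic":
            return 1.0 / r**2
        if name == "power":
            return float(np.exp(-1.0 / r))
        return r

    def range_bounds(self) -> tuple[float, float]:
        """Search domain for the kernel range parameter.

        Below 0.01 x median distance the correlation matrix is numerically
        the identity (the independent limit); above 100 x max distance it is
        indistinguishable from its large-range quadratic limit.  The REML
        profile is flat beyond both ends, so the search is restricted to
        this compact interval and a boundary optimum is reported as such.
        """
        d = self._D_obs.D[np.triu_indices(self.n, k=1)]
        d = d[d > 0]
        if len(d) == 0:
            raise ValueError("all pairwise distances are zero; spatial kernel unusable")
        return 0.01 * float(np.median(d)), 100.0 * float(np.max(d))

    def _range_grid(self, n_grid: int = 15) -> np.ndarray:
        lo, hi = self.range_bounds()
        return np.geomspace(lo, hi, n_grid)

    # ------------------------------------------------------------------- fit
    def _components(self, gamma: np.ndarray | None) -> tuple[list, set[int]]:
        comps: list[tuple[str, np.ndarray]] = []
        if gamma is not None:
            comps.append(("sigma2_g", gamma))
        ident_name = "sigma2_v" if self.spec.residual_mode == "fixed" else "sigma2_e"
        comps.append((ident_name, np.eye(self.n)))
        floor_idx: set[int] = set()
        if self.R0 is None:
            floor_idx.add(len(comps) - 1)  # keep V PD in pooled mode
        if self.omega_design is not None:
            comps.append(("sigma2_f", self.omega_design.V_f))
            comps.append(("sigma2_m", self.omega_design.V_m))
            comps.append(("sigma2_c", self.omega_design.V_c))
        return comps, floor_idx

    def _inner_fit(self, gamma: np.ndarray | None, x0=None):
        ident_name = "sigma2_v" if self.spec.residual_mode == "fixed" else "sigma2_e"
        if gamma is not None and self.R0 is None and self.omega_design is None:
            prob = _TwoComponentREML(self.y, self.X, gamma)
            variances, ll, ok, boundary, u = prob.fit(x0=x0)
            est = {"sigma2_g": variances["sigma2_g"], ident_name: variances["sigma2_I"]}
            bd = [ident_name if b == "sigma2_I" else b for b in boundary]
            return est, ll, ok, bd, u
        comps, floor_idx = self._components(gamma)
        prob = _ComponentProblem(self.y, self.X, comps, self.R0)
        if not (isinstance(x0, np.ndarray) and x0.shape == (len(comps),)):
            x0 = None
        u, ll, ok, boundary = prob.fit(x0=x0, floor_idx=floor_idx)
        return prob.variances(u), ll, ok, boundary, u

    def fit(self, theta: float | None = None, *, theta_xatol: float = 1e-4,
            n_grid: int = 13) -> "GenomicBLUPResults":
        """Maximise the REML log-likelihood; profile theta for spatial kernels.

        ``theta`` fixes the range parameter (it then does not count as an
        estimated parameter); otherwise a log-spaced grid over data-driven
        range values is refined by bounded scalar minimisation.
        """
        theta_est = None
        theta_profiled = False
        if self.kernel.name in ("independent", "rr"):
            gamma = self.gamma()
            est, ll, ok, boundary, _ = self._inner_fit(gamma)
        elif theta is not None or self.kernel.theta is not None:
            theta_est = theta if theta is not None else self.kernel.theta
            gamma = self.gamma(theta_est)
            est, ll, ok, boundary, _ = self._inner_fit(gamma)
        else:
            theta_profiled = True
            grid = self._range_grid(n_grid)
            rs: list[float] = []
            sols: list[tuple] = []
            x_prev = None

            def eval_r(r: float, x0=None):
                g = self.gamma(self._range_to_theta(r))
                return self._inner_fit(g, x0=x0)

            for r in grid:
                sol = eval_r(float(r), x0=x_prev)
                x_prev = sol[4]
                rs.append(float(r))
                sols.append(sol)

            j = max(range(len(rs)), key=lambda k: sols[k][1])
            lo = rs[max(j - 1, 0)]
            hi = rs[min(j + 1, len(rs) - 1)]
            cache: dict[float, tuple] = {}
            x_warm = sols[j][4]

            def neg_profile(logr: float) -> float:
                sol = self._inner_fit(
                    self.gamma(self._range_to_theta(float(np.exp(logr)))), x0=x_warm
                )
                cache[logr] = sol[:4]
                return -sol[1]

            if lo < hi:
                opt = minimize_scalar(
                    neg_profile,
                    bounds=(math.log(lo), math.log(hi)),
                    method="bounded",
                    options={"xatol": theta_xatol},
                )
                logr_best = float(opt.x)
                est, ll, ok, boundary = cache[logr_best]
                r_best = float(np.exp(logr_best))
            else:
                est, ll, ok, boundary, _ = sols[j]
                r_best = rs[j]
            if ll < sols[j][1]:  # keep the grid optimum if refinement regressed
                est, ll, ok, boundary, _ = sols[j]
                r_best = rs[j]
            theta_est = self._range_to_theta(r_best)
            gamma = self.gamma(theta_est)

        vc = VarianceComponents(theta=theta_est, **est)
        q = len(est) + (1 if theta_profiled else 0)
        return GenomicBLUPResults(
            model=self,
            varcomp=vc,
            llf=float(ll),
            n_covariance_params=q,
            theta_profiled=theta_profiled,
            converged=bool(ok),
            boundary=tuple(boundary),
            stabilization=self._stab_report,
            _gamma=gamma,
        )


class GenomicBLUPResults:
    """REML estimates, fit statistics and BLUP predictions for a fitted model."""

    def __init__(self, model: GenomicBLUP, varcomp: VarianceComponents, llf: float,
                 n_covariance_params: int, theta_profiled: bool, converged: bool,
                 boundary: tuple[str, ...], stabilization, _gamma):
        self.model = model
        self.varcomp = varcomp
        self.llf = llf
        self.n_covariance_params = n_covariance_params
        self.theta_profiled = theta_profiled
        self.converged = converged
        self.boundary = boundary
        self.stabilization = stabilization
        self._gamma = _gamma
        self._solve()

    # ------------------------------------------------------------- internals
    def _build_V(self) -> np.ndarray:
        m = self.model
        vc = self.varcomp
        V = np.zeros((m.n, m.n))
        if vc.sigma2_g is not None and self._gamma is not None:
            V += vc.sigma2_g * self._gamma
        V += vc.identity_variance * np.eye(m.n)
        if m.R0 is not None:
            V += np.diag(m.R0)
        if m.omega_design is not None:
            for s2, M in (
                (vc.sigma2_f, m.omega_design.V_f),
                (vc.sigma2_m, m.omega_design.V_m),
                (vc.sigma2_c, m.omega_design.V_c),
            ):
                if s2:
                    V += s2 * M
        return V

    def _solve(self) -> None:
        m = self.model
        V = self._build_V()
        scale = float(np.var(m.y, ddof=1)) or 1.0
        for jitter in (0.0, 1e-12, 1e-10, 1e-8):
            try:
                ll, beta, Py, cho = _reml_from_V(m.y, m.X, V + jitter * scale * np.eye(m.n))
                break
            except np.linalg.LinAlgError:
                if jitter == 1e-8:
                    raise
        self.mu = float(beta[0])
        resid = m.y - m.X @ beta
        self._w = sla.cho_solve(cho, resid, check_finite=False)  # V^-1 (y - mu)
        vc = self.varcomp
        self.genetic_blup = (
            vc.sigma2_g * (self._gamma @ self._w)
            if vc.sigma2_g is not None
            else np.zeros(m.n)
        )
        ident = vc.sigma2_v if vc.sigma2_v is not None else vc.sigma2_e
        self.polygenic_blup = (ident or 0.0) * self._w
        self._parent_effects: dict[str, pd.Series] = {}
        parent_part = np.zeros(m.n)
        if m.omega_design is not None:
            od = m.omega_design
            for key, s2, Z, levels in (
                ("father", vc.sigma2_f, od.Z_f, od.father_levels),
                ("mother", vc.sigma2_m, od.Z_m, od.mother_levels),
                ("cross", vc.sigma2_c, od.Z_c, od.cross_levels),
            ):
                if s2:
                    u = s2 * (Z.T @ self._w)
                    self._parent_effects[key] = pd.Series(u, index=list(levels))
                    parent_part += Z @ u
        self._parent_part = parent_part

    # ------------------------------------------------------------ public API
    @property
    def aic(self) -> float:
        """-2 * REML log-likelihood + 2 * (number of estimated covariance parameters)."""
        return -2.0 * self.llf + 2.0 * self.n_covariance_params

    @property
    def theta(self) -> float | None:
        return self.varcomp.theta

    @property
    def lambda2(self) -> float | None:
        """Ridge penalty lambda^2 = sigma2_e / sigma2_g (pooled-residual fits)."""
        vc = self.varcomp
        if vc.sigma2_g and vc.sigma2_e is not None:
            return vc.sigma2_e / vc.sigma2_g if vc.sigma2_g > 0 else math.inf
        return None

    @property
    def fittedvalues(self) -> pd.Series:
        return pd.Series(
            self.mu + self.genetic_blup + self.polygenic_blup + self._parent_part,
            index=list(self.model.ids),
            name="fitted",
        )

    @property
    def gebv(self) -> pd.Series:
        """GEBVs of the training individuals: mu + g_hat (+ parent effects)."""
        return pd.Series(
            self.mu + self.genetic_blup + self._parent_part,
            index=list(self.model.ids),
            name="gebv",
        )

    def ridge_effects(self) -> np.ndarray:
        """Marker-effect ridge solution u = (Z'Z + lambda^2 I)^-1 Z'(y - mu) (rr only)."""
        if self.model.kernel.name != "rr":
            raise ValueError("marker effects are defined for the rr kernel only")
        lam2 = self.lambda2
        if lam2 is None:
            raise ValueError("lambda^2 undefined (no pooled residual variance)")
        Z = self.model.Z_obs.Z
        mmat = Z.T @ Z + lam2 * np.eye(Z.shape[1])
        resid = self.model.y - self.mu
        return np.linalg.solve(mmat, Z.T @ resid)

    def predict(self, genotypes: GenotypeMatrix | None = None,
                ids=None, pedigree: Pedigree | None = None) -> pd.Series:
        """GEBVs for (typically unphenotyped) individuals.

        By default predicts every individual in the model's genotype matrix
        that is not in the training set.  Independent polygenic effects
        contribute nothing out of sample; father/mother/cross effects are
        added for individuals whose parents appear in the training levels
        (requires a pedigree covering the new ids).
        """
        m = self.model
        if genotypes is None:
            pool = ids if ids is not None else [
                i for i in m.genotypes.individual_ids if i not in set(m.ids)
            ]
            genotypes = m.genotypes.subset(pool)
        new_ids = list(genotypes.individual_ids)
        vc = self.varcomp
        if vc.sigma2_g is not None and vc.sigma2_g > 0 and m.kernel.name != "independent":
            if m.kernel.name == "rr":
                G_cross = genotypes.Z @ m.Z_obs.Z.T
            else:
                Dx = cross_distance(genotypes, m.Z_obs)
                G_cross = np.asarray(kernel_value(m.kernel.name, Dx, vc.theta))
            g_new = vc.sigma2_g * (G_cross @ self._w)
        else:
            g_new = np.zeros(len(new_ids))
        pred = self.mu + g_new
        ped = pedigree or m.pedigree
        if self._parent_effects and ped is not None:
            for j, ind in enumerate(new_ids):
                for key, col in (("father", "father"), ("mother", "mother"), ("cross", "cross")):
                    if key in self._parent_effects and ind in ped.table.index:
                        level = ped.table.loc[ind, col]
                        eff = self._parent_effects[key]
                        if level in eff.index:
                            pred[j] += eff[level]
        return pd.Series(pred, index=new_ids, name="gebv")

    def gebv_table(self) -> pd.DataFrame:
        """GEBVs for every genotyped individual with a phenotyped flag."""
        train = self.gebv
        new = self.predict()
        rows = pd.concat(
            [
                pd.DataFrame({"gebv": train, "phenotyped": True}),
                pd.DataFrame({"gebv": new, "phenotyped": False}),
            ]
        )
        rows.index.name = "individual"
        return rows

    def summary(self) -> str:
        m = self.model
        vc = self.varcomp
        lines = [
            "Genomic BLUP (REML) results",
            "=" * 44,
            f"kernel:            {m.kernel.name}",
            f"residual mode:     {m.spec.residual_mode}",
            f"pedigree mode:     {m.spec.pedigree_mode}",
            f"n (phenotyped):    {m.n}",
            f"markers:           {m.genotypes.n_markers}",
            "-" * 44,
        ]
        for name, value in vc.as_dict().items():
            flag = "  (boundary)" if name in self.boundary else ""
            lines.append(f"{name:<12s} {value:>14.6g}{flag}")
        if self.lambda2 is not None:
            lines.append(f"{'lambda^2':<12s} {self.lambda2:>14.6g}")
        lines += [
            "-" * 44,
            f"mu (intercept):    {self.mu:.6g}",
            f"REML log-lik:      {self.llf:.4f}",
            f"AIC:               {self.aic:.4f}   (q = {self.n_covariance_params})",
            f"converged:         {self.converged}",
        ]
        if self.stabilization is not None and self.stabilization.adjusted:
            lines.append(
                f"Gamma stabilized:  {self.stabilization.policy} "
                f"(min eig {self.stabilization.min_eigenvalue_before:.3g} -> "
                f"{self.stabilization.min_eigenvalue_after:.3g})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kernel": self.model.kernel.name,
            "residual_mode": self.model.spec.residual_mode,
            "pedigree_mode": self.model.spec.pedigree_mode,
            "varcomp": self.varcomp.as_dict(),
            "boundary": list(self.boundary),
            "mu": self.mu,
            "reml_loglik": self.llf,
            "aic": self.aic,
            "n_covariance_params": self.n_covariance_params,
            "converged": self.converged,
            "lambda2": self.lambda2,
            "gamma_stabilized": bool(self.stabilization and self.stabilization.adjusted),
        }


# --------------------------------------------------------------- thin wrappers
def fit_model(
    spec: ModelSpec,
    y: pd.Series,
    genotypes: GenotypeMatrix,
    *,
    error_variances: pd.Series | None = None,
    pedigree: Pedigree | None = None,
    theta: float | None = None,
) -> GenomicBLUPResults:
    """Fit one :class:`ModelSpec`; convenience wrapper around :class:`GenomicBLUP`."""
    model = GenomicBLUP(
        y,
        genotypes,
        kernel=spec.kernel,
        residual="fixed" if spec.residual_mode == "fixed" else "pooled",
        error_variances=error_variances,
        pedigree=pedigree if spec.pedigree_mode == "on" else None,
    )
    return model.fit(theta=theta)


def blup_gebv(results: GenomicBLUPResults) -> pd.DataFrame:
    """GEBV table (phenotyped + predicted individuals) for a fitted model."""
    return results.gebv_table()


def aic(results: GenomicBLUPResults) -> float:
    return results.aic
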