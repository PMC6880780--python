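"""Fitting machinery for the joint dMRI-microscopy model.

Two fitters are provided:

* :func:`fit_joint` -- the full 30-parameter model (2 tensor diffusivities +
  28 SH coefficients) minimising E = E_diff + lambda_micro*E_micro +
  lambda_complex*E_complex under d_axial >= d_radial >= 0, with a small
  multistart scheme (annealing-style perturbation of the initial point).

* :func:`sample_watson_posterior` -- the simplified 3-parameter model used in
  the validation experiments: the FOD is a Watson distribution with a fixed
  peak axis, fully characterised by its ODI, so the free parameters are
  (ODI, d_axial, d_radial). It is fitted by adaptive random-walk Metropolis,
  which exposes parameter degeneracies (flat cost ridges) as correlated
  posterior samples. The log-target is the exact Gaussian log-likelihood of
  the dMRI data, -N*E_diff/(2*sigma^2), with the microscopy term entering on
  the same scale weighted by lambda_micro; no complexity penalty is used in
  the simplified model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize
from scipy.special import eval_legendre

from .forward import (
    FLOOR,
    AcquisitionScheme,
    MicroFOD2D,
    ResponseFunction,
    SphereWorkspace,
)
from .objective import CostBreakdown, total_cost
from .spherical import SHCoefficients, sh_basis_matrix, sh_basis_size, sh_degrees
from .synthetic import (
    WatsonParams,
    kappa_from_odi,
    odi_from_kappa,
    _watson_norm_shifted,
)

__all__ = [
    "odi_from_kappa",
    "kappa_from_odi",
    "FitError",
    "JointFitResult",
    "WatsonPosterior",
    "SimplifiedWatsonModel",
    "watson_loglike",
    "sample_watson_posterior",
    "fit_joint",
]

_D_MAX = 4.0  # um^2/ms box bound on diffusivities


class FitError(RuntimeError):
    """Raised when the joint-model optimisation fails on every start."""


@dataclass
class JointFitResult:
    """Best-of-multistart joint fit: response function, FOD and cost breakdown."""

    frf: ResponseFunction
    fod: SHCoefficients
    cost: CostBreakdown
    n_starts: int
    start_costs: list[float]


@dataclass
class WatsonPosterior:
    """Post-burn-in MCMC samples of (ODI, d_axial, d_radial)."""

    samples: np.ndarray  # (M, 3)
    acceptance_rate: float
    fixed_peak: tuple[float, float]
    log_post: np.ndarray = field(default=None, repr=False)

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)

    def corr_odi_dradial(self) -> float:
        """Pearson correlation of ODI and d_radial samples (degeneracy marker)."""
        return float(np.corrcoef(self.samples[:, 0], self.samples[:, 2])[0, 1])

    def central_interval(self, level: float = 0.95) -> np.ndarray:
        a = (1 - level) / 2
        return np.quantile(self.samples, [a, 1 - a], axis=0)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=["odi", "d_axial", "d_radial"])
        if self.log_post is not None:
            df["logpost"] = self.log_post
        df.to_csv(path, index_label="iteration")


class SimplifiedWatsonModel:
    """Precomputed likelihood for the 3-parameter (ODI, d_axial, d_radial) model.

    The FOD is a Watson distribution with a fixed mean axis, band-limited to
    the workspace order (6), negativity-clipped, then convolved with the tensor
    FRF for the dMRI term and projected to the in-plane histogram for the
    microscopy term -- exactly the forward model of the full fit, with the 28
    SH coefficients replaced by the one-parameter Watson family.
    """

    def __init__(
        self,
        Y: np.ndarray,
        scheme: AcquisitionScheme,
        micro: MicroFOD2D | None,
        fixed_peak: tuple[float, float] = (0.0, 0.0),
        lambda_micro: float = 1.0,
        sigma: float = 1.0 / 15.0,
        workspace: SphereWorkspace | None = None,
        plane_normal=(0.0, 0.0, 1.0),
    ):
        self.workspace = workspace if workspace is not None else SphereWorkspace()
        shell = scheme.shell()
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.shape != (shell.n,):
            raise ValueError("data length must match the diffusion-weighted scheme")
        self.b_value = float(shell.b_values[0])
        self.micro = micro
        self.lambda_micro = float(lambda_micro)
        if self.lambda_micro != 0.0 and micro is None:
            raise ValueError("microscopy FOD required when lambda_micro != 0")
        self.sigma = float(sigma)
        self.fixed_peak = tuple(fixed_peak)
        mu = WatsonParams(theta=fixed_peak[0], phi=fixed_peak[1], kappa=1.0).mu
        sph = self.workspace.sphere
        self._mu_dot2 = (sph.directions @ mu) ** 2
        self._B = self.workspace.B
        self._P = self.workspace.pinvB
        self._w = sph.weights
        self._B_scheme = sh_basis_matrix(self.workspace.lmax, shell.directions)
        self._deg_half = sh_degrees(self.workspace.lmax) // 2
        self._gl_t, self._gl_w = leggauss(64)
        ls = np.arange(0, self.workspace.lmax + 1, 2)
        self._legendre = np.stack([eval_legendre(l, self._gl_t) for l in ls])
        if micro is not None:
            self._wedge = self.workspace.wedge_matrix(plane_normal, micro.n_bins)
            self._n_bins = micro.n_bins

    def in_support(self, params) -> bool:
        odi, d_a, d_r = params
        return (0.0 < odi < 1.0) and (0.0 <= d_r <= d_a <= _D_MAX)

    def cost(self, params) -> tuple[float, float, float]:
        """(E, E_diff, E_micro) of Eq-2 form with lambda_complex = 0."""
        odi, d_a, d_r = params
        kappa = kappa_from_odi(odi)
        dens = np.exp(kappa * (self._mu_dot2 - 1.0)) / _watson_norm_shifted(kappa)
        c = self._P @ dens
        amps = self._B @ c
        np.maximum(amps, 0.0, out=amps)
        c_clip = self._P @ amps
        b = self.b_value * 1e-3
        profile = np.exp(-b * (d_r + (d_a - d_r) * self._gl_t**2))
        f_l = 2 * np.pi * (self._legendre @ (self._gl_w * profile))
        s = self._B_scheme @ (c_clip * f_l[self._deg_half])
        e_diff = float(np.mean((self.Y - s) ** 2))
        e_micro = 0.0
        if self.micro is not None:
            masses = np.maximum(self._wedge @ c_clip, 0.0)
            tot = masses.sum()
            q = masses / tot if tot > 0 else np.full(self._n_bins, 1.0 / self._n_bins)
            np.maximum(q, FLOOR, out=q)
            q /= q.sum()
            p = self.micro.probs
            e_micro = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
        return e_diff + self.lambda_micro * e_micro, e_diff, e_micro

    def log_target(self, params) -> float:
        """Gaussian log-likelihood mapping of the cost; -inf outside constraints."""
        if not self.in_support(params):
            return -np.inf
        e, _, _ = self.cost(params)
        return -len(self.Y) * e / (2.0 * self.sigma**2)


def watson_loglike(
    Y: np.ndarray,
    scheme: AcquisitionScheme,
    micro: MicroFOD2D | None,
    params,
    fixed_peak=(0.0, 0.0),
    lambda_micro: float = 1.0,
    sigma: float = 1.0 / 15.0,
    workspace: SphereWorkspace | None = None,
) -> float:
    """One-shot simplified-model log-target (see :class:`SimplifiedWatsonModel`)."""
    model = SimplifiedWatsonModel(
        Y, scheme, micro, fixed_peak, lambda_micro, sigma, workspace
    )
    return model.log_target(params)


def sample_watson_posterior(
    Y: np.ndarray,
    scheme: AcquisitionScheme,
    micro: MicroFOD2D | None,
    lambda_micro: float,
    n_iter: int = 20_000,
    seed=0,
    init=(0.5, 0.25, 0.05),
    fixed_peak=(0.0, 0.0),
    sigma: float = 1.0 / 15.0,
    workspace: SphereWorkspace | None = None,
    plane_normal=(0.0, 0.0, 1.0),
) -> WatsonPosterior:
    """Adaptive random-walk Metropolis over (ODI, d_axial, d_radial).

    Proposal scales (and, from halfway through the window, the full proposal
    covariance) adapt over the first 20% of iterations and are then frozen so
    the remaining chain targets the exact posterior; the first 30% is discarded
    as burn-in. Reproducible given ``seed``.
    """
    model = SimplifiedWatsonModel(
        Y, scheme, micro, fixed_peak, lambda_micro, sigma, workspace, plane_normal
    )
    rng = np.random.default_rng(seed)
    x = np.asarray(init, dtype=float)
    if not model.in_support(x):
        raise ValueError(f"initial parameters {x} violate constraints")
    lp = model.log_target(x)
    n_adapt = int(0.2 * n_iter)
    n_burn = int(0.3 * n_iter)
    scale = np.array([0.05, 0.02, 0.02])
    cov_chol = None
    chain = np.empty((n_iter, 3))
    lps = np.empty(n_iter)
    accepted_recent = 0
    accepted_total = 0
    for it in range(n_iter):
        if cov_chol is None:
            prop = x + scale * rng.standard_normal(3)
        else:
            prop = x + cov_chol @ rng.standard_normal(3)
        lp_prop = model.log_target(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted_recent += 1
            accepted_total += 1
        chain[it] = x
        lps[it] = lp
        if it < n_adapt and (it + 1) % 100 == 0:
            rate = accepted_recent / 100.0
            accepted_recent = 0
            scale *= np.exp(rate - 0.25)
            if it + 1 >= max(n_adapt // 2, 300):
                cov = np.cov(chain[max(0, it - n_adapt // 2) : it + 1].T)
                cov = (2.38**2 / 3.0) * cov + 1e-10 * np.eye(3)
                try:
                    cov_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    cov_chol = None
    acc_rate = accepted_total / n_iter
    if not 0.05 <= acc_rate <= 0.8:
        warnings.warn(f"MCMC acceptance rate {acc_rate:.3f} outside [0.05, 0.8]")
    return WatsonPosterior(
        samples=chain[n_burn:],
        acceptance_rate=acc_rate,
        fixed_peak=model.fixed_peak,
        log_post=lps[n_burn:],
    )


class JointCostEvaluator:
    """Precomputed evaluator of the full 30-parameter cost.

    Numerically identical to :func:`fodfusion.objective.total_cost` (asserted
    by the test suite) but caches the scheme basis, the per-order Legendre
    quadrature and the 2D wedge operator, which dominate the cost of repeated
    evaluations inside the optimiser.
    """

    def __init__(
        self,
        Y: np.ndarray,
        micro: MicroFOD2D | None,
        scheme: AcquisitionScheme,
        lambda_micro: float,
        lambda_complex: float,
        workspace: SphereWorkspace,
        plane_normal=(0.0, 0.0, 1.0),
    ):
        scheme.shell()  # validates the single-shell restriction
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.shape != (scheme.n,):
            raise ValueError("data length must match the scheme")
        self.micro = micro
        self.lambda_micro = float(lambda_micro)
        self.lambda_complex = float(lambda_complex)
        self.workspace = workspace
        lmax = workspace.lmax
        self._deg_half = sh_degrees(lmax) // 2
        self._gl_t, self._gl_w = leggauss(64)
        ls = np.arange(0, lmax + 1, 2)
        self._legendre = np.stack([eval_legendre(l, self._gl_t) for l in ls])
        B_all = sh_basis_matrix(lmax, scheme.directions)
        self._groups = [
            (float(b), scheme.b_values == b, B_all[scheme.b_values == b])
            for b in np.unique(scheme.b_values)
        ]
        self._n = scheme.n
        if micro is not None:
            self._wedge = workspace.wedge_matrix(plane_normal, micro.n_bins)

    def f_l(self, d_axial: float, d_radial: float, b: float) -> np.ndarray:
        profile = np.exp(
            -b * 1e-3 * (d_radial + (d_axial - d_radial) * self._gl_t**2)
        )
        return 2 * np.pi * (self._legendre @ (self._gl_w * profile))

    def cost(self, d_axial: float, d_radial: float, coeffs: np.ndarray) -> CostBreakdown:
        ws = self.workspace
        amps = ws.B @ coeffs
        neg = np.minimum(amps, 0.0)
        e_neg = float(-(ws.sphere.weights * neg).sum())
        c_clip = ws.pinvB @ (amps - neg)
        S = np.empty(self._n)
        for b, rows, B_rows in self._groups:
            S[rows] = B_rows @ (c_clip * self.f_l(d_axial, d_radial, b)[self._deg_half])
        e_diff_val = float(np.mean((self.Y - S) ** 2))
        e_micro_val = 0.0
        if self.micro is not None:
            masses = np.maximum(self._wedge @ c_clip, 0.0)
            tot = masses.sum()
            if tot > 0:
                q = masses / tot
            else:
                q = np.full(len(masses), 1.0 / len(masses))
            np.maximum(q, FLOOR, out=q)
            q /= q.sum()
            np.maximum(q, FLOOR, out=q)
            p = self.micro.probs
            e_micro_val = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
        e_complex_val = e_neg + float(np.abs(coeffs).sum())
        return CostBreakdown.combine(
            e_diff_val, e_micro_val, e_complex_val, e_neg,
            self.lambda_micro, self.lambda_complex,
        )


def _pack(frf: ResponseFunction, fod: SHCoefficients) -> np.ndarray:
    # internal parametrisation: (d_radial, d_axial - d_radial, coeffs...) keeps
    # the d_axial >= d_radial >= 0 constraint as simple box bounds
    return np.concatenate(
        [[frf.d_radial, frf.d_axial - frf.d_radial], fod.coeffs]
    )


def _unpack(z: np.ndarray, b_value: float, lmax: int):
    d_r, delta = max(z[0], 0.0), max(z[1], 0.0)
    frf = ResponseFunction(d_axial=d_r + delta, d_radial=d_r, b_value=b_value)
    return frf, SHCoefficients(lmax, z[2:])


def fit_joint(
    Y: np.ndarray,
    micro: MicroFOD2D | None,
    scheme: AcquisitionScheme,
    lambda_micro: float = 1.0,
    lambda_complex: float = 1e-3,
    init_frf: ResponseFunction | None = None,
    init_fod: SHCoefficients | None = None,
    workspace: SphereWorkspace | None = None,
    n_starts: int = 3,
    n_anneal: int = 100,
    maxiter: int = 500,
    seed=0,
    plane_normal=(0.0, 0.0, 1.0),
) -> JointFitResult:
    """Multistart constrained fit of the 30-parameter joint model.

    The default initialisation is the one used on real data: the FOD from CSD
    (pass ``init_fod``) and the FRF at d_axial = 0.25, d_radial = 0.05
    um^2/ms. ``n_starts - 1`` extra starting points are produced by a short
    annealing-style randomised search (temperature-decayed Gaussian jumps)
    around the initial point; each start is refined with a box-constrained
    quasi-Newton optimiser and the solution with the lowest cost is returned
    (ties broken by lowest complexity term).
    """
    workspace = workspace if workspace is not None else SphereWorkspace()
    lmax = workspace.lmax
    shell = scheme.shell()
    b_value = float(shell.b_values[0])
    if init_frf is None:
        init_frf = ResponseFunction(d_axial=0.25, d_radial=0.05, b_value=b_value)
    if init_fod is None:
        c0 = np.zeros(sh_basis_size(lmax))
        c0[0] = 1.0 / np.sqrt(4 * np.pi)  # unit-mass isotropic FOD
        init_fod = SHCoefficients(lmax, c0)

    evaluator = JointCostEvaluator(
        Y, micro, scheme, lambda_micro, lambda_complex, workspace, plane_normal
    )

    def cost_of(z: np.ndarray) -> CostBreakdown:
        return evaluator.cost(z[0] + z[1], z[0], z[2:])

    def f(z: np.ndarray) -> float:
        return cost_of(z).E

    # The cost surface couples the diffusivities to a per-order rescaling of
    # the FOD along a very flat valley (a small signal misfit can compensate a
    # large diffusivity change), which stalls direct quasi-Newton descent. A
    # nested warm start avoids this: for candidate diffusivities the FOD is
    # profiled out by linear least squares on the signal, and the full cost of
    # that profiled FOD is minimised over the two diffusivities alone.
    Yd = np.asarray(Y, dtype=float)
    deg_half = sh_degrees(lmax) // 2

    def profiled(d_pair: np.ndarray) -> np.ndarray:
        d_r = float(np.clip(d_pair[0], 0.0, _D_MAX))
        delta = float(np.clip(d_pair[1], 0.0, _D_MAX))
        M = np.concatenate(
            [
                B_rows * evaluator.f_l(d_r + delta, d_r, b)[deg_half]
                for b, rows, B_rows in evaluator._groups
            ]
        )
        Y_grouped = np.concatenate(
            [Yd[rows] for _, rows, _ in evaluator._groups]
        )
        c, *_ = np.linalg.lstsq(M, Y_grouped, rcond=None)
        return np.concatenate([[d_r, delta], c])

    prof = minimize(
        lambda d: f(profiled(d)),
        [init_frf.d_radial, init_frf.d_axial - init_frf.d_radial],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxfev": 120},
    )
    z0 = _pack(init_frf, init_fod)
    warm = profiled(prof.x)
    rng = np.random.default_rng(seed)
    starts = [warm if f(warm) < f(z0) else z0]
    step0 = np.concatenate([[0.05, 0.05], 0.05 * np.ones(len(z0) - 2)])
    for _ in range(n_starts - 1):
        z, fz = starts[0].copy(), f(starts[0])
        best_z, best_f = z, fz
        for k in range(n_anneal):
            temp = max(1.0 - k / n_anneal, 1e-3)
            cand = z + temp * step0 * rng.standard_normal(len(z))
            cand[:2] = np.clip(cand[:2], 0.0, _D_MAX)
            fc = f(cand)
            if fc < fz or rng.uniform() < np.exp(-(fc - fz) / max(temp * fz, 1e-12)):
                z, fz = cand, fc
                if fz < best_f:
                    best_z, best_f = z, fz
        starts.append(best_z)

    bounds = [(0.0, _D_MAX), (0.0, _D_MAX)] + [(None, None)] * (len(z0) - 2)
    results = []
    for z_start in starts:
        try:
            res = minimize(
                f, z_start, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
            )
            if np.isfinite(res.fun):
                results.append(res)
        except Exception as exc:  # pragma: no cover - optimiser failure path
            warnings.warn(f"optimiser start failed: {exc}")
    if not results:
        raise FitError(f"all {n_starts} optimisation starts failed")
    costs = [cost_of(r.x) for r in results]
    order = sorted(
        range(len(results)), key=lambda i: (costs[i].E, costs[i].E_complex)
    )
    best = order[0]
    frf, fod = _unpack(results[best].x, b_value, lmax)
    return JointFitResult(
        frf=frf,
        fod=fod,
        cost=costs[best],
        n_starts=len(starts),
        start_costs=[c.E for c in costs],
    )
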