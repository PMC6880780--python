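"""Constrained spherical deconvolution baseline and a global response-function
estimator, used to initialise the joint model and for comparison.

The response function is estimated from the highest-FA voxels (axially
symmetrised log-linear tensor fits); the FOD is recovered by least-squares
spherical deconvolution with an iterative soft negativity constraint
(Tikhonov-style penalty rows added wherever the FOD amplitude drops below a
fraction tau of its mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import (
    AcquisitionScheme,
    ResponseFunction,
    SphereWorkspace,
    frf_rotational_harmonics,
)
from .spherical import SHCoefficients, sh_basis_matrix, sh_degrees

__all__ = ["TensorFit", "fit_tensor", "estimate_global_frf", "csd_fit"]


@dataclass
class TensorFit:
    """Per-voxel diffusion tensor summary (diffusivities in um^2/ms)."""

    eigenvalues: np.ndarray  # (..., 3) sorted descending
    fa: np.ndarray  # (...,)
    principal: np.ndarray  # (..., 3) unit eigenvector of the largest eigenvalue


def fit_tensor(Y: np.ndarray, scheme: AcquisitionScheme) -> TensorFit:
    """Log-linear least-squares tensor fit on attenuations.

    ``Y`` has shape (..., N) over the diffusion-weighted directions of the
    scheme's single shell. Non-positive attenuations are clipped at 1e-6 with
    a warning before taking logs.
    """
    shell = scheme.shell()
    if shell.n < 6:
        raise ValueError("tensor fit needs at least 6 directions")
    Y = scheme.dw_subset(Y)
    if np.any(Y <= 0):
        warnings.warn("non-positive attenuations clipped at 1e-6 for the log fit")
        Y = np.clip(Y, 1e-6, None)
    g = shell.directions
    b = shell.b_values[:, None] * 1e-3  # ms/um^2
    # log A = -b g^T D g; unknowns (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    X = -b * np.column_stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ]
    )
    flat = np.log(Y).reshape(-1, shell.n)
    d, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    d = d.T  # (V, 6)
    D = np.empty((len(d), 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = d[:, 0], d[:, 1], d[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = d[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = d[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = d[:, 5]
    evals, evecs = np.linalg.eigh(D)
    evals = evals[:, ::-1]
    principal = evecs[:, :, ::-1][:, :, 0]
    mean_ev = evals.mean(axis=1, keepdims=True)
    num = np.sum((evals - mean_ev) ** 2, axis=1)
    den = np.sum(evals**2, axis=1)
    fa = np.sqrt(1.5 * np.divide(num, den, out=np.zeros_like(num), where=den > 0))
    shape = Y.shape[:-1]
    return TensorFit(
        eigenvalues=evals.reshape(shape + (3,)),
        fa=np.clip(fa, 0.0, 1.0).reshape(shape),
        principal=principal.reshape(shape + (3,)),
    )


def estimate_global_frf(
    Y_volume: np.ndarray,
    scheme: AcquisitionScheme,
    n_voxels: int = 300,
    mask: np.ndarray | None = None,
) -> ResponseFunction:
    """Global FRF from the ``n_voxels`` highest-FA voxels.

    Each selected voxel's tensor is axially symmetrised (d_axial = lambda_1,
    d_radial = (lambda_2 + lambda_3)/2) and the diffusivities averaged. In
    dispersed tissue this conflates dispersion with diffusivity, inflating
    d_radial relative to the true single-fibre value.
    """
    Y_volume = np.asarray(Y_volume, dtype=float)
    flat = Y_volume.reshape(-1, Y_volume.shape[-1])
    if mask is not None:
        flat = flat[np.asarray(mask, dtype=bool).reshape(-1)]
    if len(flat) < n_voxels:
        raise ValueError(
            f"mask has {len(flat)} voxels, fewer than n_voxels={n_voxels}"
        )
    tf = fit_tensor(flat, scheme)
    top = np.argsort(tf.fa)[::-1][:n_voxels]
    ev = tf.eigenvalues[top]
    d_axial = float(ev[:, 0].mean())
    d_radial = float(ev[:, 1:].mean())
    d_axial = max(d_axial, 0.0)
    d_radial = min(max(d_radial, 0.0), d_axial)
    return ResponseFunction(
        d_axial=d_axial, d_radial=d_radial, b_value=float(scheme.shell().b_values[0])
    )


def csd_fit(
    Y: np.ndarray,
    frf: ResponseFunction,
    scheme: AcquisitionScheme,
    lmax: int = 6,
    n_iter: int = 50,
    tau: float = 0.1,
    reg_weight: float = 1.0,
    workspace: SphereWorkspace | None = None,
    return_info: bool = False,
):
    """Constrained spherical deconvolution of a single voxel's attenuations.

    An unconstrained least-squares SH deconvolution is refined by iteratively
    adding soft penalty rows at dense-sphere directions where the FOD falls
    below ``tau`` times its mean amplitude, until the constrained set
    stabilises or ``n_iter`` is reached.
    """
    workspace = workspace if workspace is not None else SphereWorkspace(lmax=lmax)
    shell = scheme.shell()
    Y = scheme.dw_subset(Y)
    rh = frf_rotational_harmonics(frf, lmax)
    B_scheme = sh_basis_matrix(lmax, shell.directions)
    M = B_scheme * rh.f_l[sh_degrees(lmax) // 2]
    B = workspace.B

    def solve(constrained: np.ndarray) -> np.ndarray:
        if constrained.any():
            L = B[constrained]
            scale = reg_weight * np.linalg.norm(M) / max(np.linalg.norm(L), 1e-12)
            A = np.vstack([M, scale * L])
            rhs = np.concatenate([Y, np.zeros(int(constrained.sum()))])
        else:
            A, rhs = M, Y
        try:
            c, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate systems
            warnings.warn("ill-conditioned deconvolution; adding ridge fallback")
            c = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ rhs)
        return c

    c = solve(np.zeros(workspace.sphere.n, dtype=bool))
    amps0 = B @ c
    threshold = tau * max(float(amps0.mean()), 0.0)
    history = [float(np.mean((Y - M @ c) ** 2))]
    constrained = np.zeros(workspace.sphere.n, dtype=bool)
    for _ in range(n_iter):
        amps = B @ c
        new_constrained = amps < threshold
        if np.array_equal(new_constrained, constrained):
            break
        constrained = new_constrained
        c = solve(constrained)
        history.append(float(np.mean((Y - M @ c) ** 2)))
    fod = SHCoefficients(lmax, c)
    if return_info:
        return fod, {"e_diff_history": history, "n_constrained": int(constrained.sum())}
    return fod
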