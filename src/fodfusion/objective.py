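"""The three-term joint-model cost: E = E_diff + lambda_micro*E_micro + lambda_complex*E_complex.

E_diff is the mean squared error between measured and predicted attenuations;
E_micro the symmetric Kullback-Leibler divergence (natural log) between the
microscopy 2D FOD and the projected model FOD; E_complex penalises negative
FOD lobes (E_neg) plus the L1 norm of all SH coefficients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .forward import (
    AcquisitionScheme,
    MicroFOD2D,
    ResponseFunction,
    SphereWorkspace,
    clip_negative,
    frf_rotational_harmonics,
)
from .spherical import DenseSphere, SHCoefficients, convolve, sh_basis_size

__all__ = ["CostBreakdown", "e_diff", "e_micro", "e_complex", "total_cost"]


@dataclass
class CostBreakdown:
    """All cost components of one model evaluation, for logging and fitting."""

    E: float
    E_diff: float
    E_micro: float
    E_complex: float
    E_neg: float
    lambda_micro: float
    lambda_complex: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def combine(
        cls,
        e_diff_val: float,
        e_micro_val: float,
        e_complex_val: float,
        e_neg_val: float,
        lambda_micro: float,
        lambda_complex: float,
    ) -> "CostBreakdown":
        total = e_diff_val + lambda_micro * e_micro_val + lambda_complex * e_complex_val
        return cls(
            E=total,
            E_diff=e_diff_val,
            E_micro=e_micro_val,
            E_complex=e_complex_val,
            E_neg=e_neg_val,
            lambda_micro=lambda_micro,
            lambda_complex=lambda_complex,
        )


def e_diff(Y: np.ndarray, S: np.ndarray) -> float:
    """Mean squared error between measured and predicted attenuations."""
    Y = np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if Y.shape != S.shape or Y.ndim != 1 or len(Y) < 1:
        raise ValueError(f"attenuation vectors must match, got {Y.shape} vs {S.shape}")
    return float(np.mean((Y - S) ** 2))


def e_micro(P: MicroFOD2D, Q: MicroFOD2D) -> float:
    """Symmetric KL divergence D(P||Q) + D(Q||P) in nats.

    Both inputs carry the 2e-16 bin floor, so the value is always finite;
    zero iff the histograms agree bin-wise.
    """
    if not P.same_binning(Q):
        raise ValueError("2D FOD histograms must share the same binning")
    p, q = P.probs, Q.probs
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def e_complex(
    fod: SHCoefficients, sphere: DenseSphere, _clip=clip_negative
) -> tuple[float, float]:
    """Complexity penalty: E_neg plus the L1 norm of the 28 SH coefficients."""
    if len(fod.coeffs) != sh_basis_size(6):
        raise ValueError("complexity penalty is defined for lmax = 6 (28 coefficients)")
    _, e_neg_val = _clip(fod, sphere)
    return e_neg_val + float(np.abs(fod.coeffs).sum()), e_neg_val


def total_cost(
    Y: np.ndarray,
    micro: MicroFOD2D,
    frf: ResponseFunction,
    fod: SHCoefficients,
    scheme: AcquisitionScheme,
    lambda_micro: float,
    lambda_complex: float,
    workspace: SphereWorkspace | None = None,
    plane_normal=(0.0, 0.0, 1.0),
) -> CostBreakdown:
    """Evaluate the full joint-model cost for one parameter set.

    The predicted signal and the 2D projection both use the negativity-clipped
    FOD; clipping is done once and shared across the three terms.
    """
    if workspace is None:
        workspace = SphereWorkspace(lmax=fod.lmax)
    scheme.shell()  # validates the single-shell restriction
    amps, e_neg_val = workspace.clip(fod)
    c_clip = workspace.analyse(amps)
    S = np.empty(scheme.n)
    for b in np.unique(scheme.b_values):
        rows = scheme.b_values == b
        rh = frf_rotational_harmonics(
            ResponseFunction(frf.d_axial, frf.d_radial, b), fod.lmax
        )
        S[rows] = convolve(c_clip, rh, scheme.directions[rows])
    e_diff_val = e_diff(Y, S)
    e_micro_val = 0.0
    if micro is not None:
        joint2d = workspace.project_2d(c_clip, plane_normal, micro.n_bins)
        e_micro_val = e_micro(micro, joint2d)
    elif lambda_micro != 0.0:
        raise ValueError("a microscopy 2D FOD is required when lambda_micro != 0")
    e_complex_val = e_neg_val + float(np.abs(fod.coeffs).sum())
    return CostBreakdown.combine(
        e_diff_val, e_micro_val, e_complex_val, e_neg_val, lambda_micro, lambda_complex
    )
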