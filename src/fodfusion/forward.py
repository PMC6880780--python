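"""Generative forward model: tensor fibre response, predicted dMRI attenuation,
FOD negativity handling, and projection of the 3D FOD onto the microscopy plane.

The fibre response function (FRF) is an axially symmetric diffusion tensor with
diffusivities d_axial >= d_radial >= 0 (um^2/ms). Its attenuation profile at
angle gamma from the fibre axis is

    exp(-b * (d_radial + (d_axial - d_radial) * cos(gamma)^2))

with b converted from s/mm^2 to ms/um^2 so the exponent is dimensionless.
Predicted signals are attenuations (DWI normalised by the mean b~0 image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spherical import (
    DenseSphere,
    RotationalHarmonics,
    SHCoefficients,
    convolve,
    dense_sphere,
    eval_sh,
    kernel_rh,
    sh_basis_matrix,
)

__all__ = [
    "FLOOR",
    "ResponseFunction",
    "AcquisitionScheme",
    "MicroFOD2D",
    "frf_signal",
    "frf_rotational_harmonics",
    "predict_signal",
    "clip_negative",
    "project_fod_2d",
    "plane_basis",
    "fold_azimuth",
    "SphereWorkspace",
    "default_sphere",
]

#: Lower bound applied to 2D FOD histogram bins so KL divergences stay finite.
FLOOR = 2e-16

_DEFAULT_SPHERE: DenseSphere | None = None


def default_sphere() -> DenseSphere:
    """Shared level-4 icosphere (2562 directions) used when none is given."""
    global _DEFAULT_SPHERE
    if _DEFAULT_SPHERE is None:
        _DEFAULT_SPHERE = dense_sphere(4)
    return _DEFAULT_SPHERE


@dataclass
class ResponseFunction:
    """Axially symmetric tensor FRF: diffusivities in um^2/ms, b in s/mm^2."""

    d_axial: float
    d_radial: float
    b_value: float

    def __post_init__(self) -> None:
        if not (self.d_axial >= self.d_radial >= 0):
            raise ValueError(
                f"require d_axial >= d_radial >= 0, got "
                f"({self.d_axial}, {self.d_radial})"
            )
        if self.b_value < 0:
            raise ValueError("b_value must be non-negative")


@dataclass
class AcquisitionScheme:
    """Diffusion gradient table: unit directions and b-values (s/mm^2)."""

    directions: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.b_values = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        if self.directions.shape != (len(self.b_values), 3):
            raise ValueError("directions must be (N, 3) matching b_values")
        if len(self.b_values) < 1 or np.any(self.b_values < 0):
            raise ValueError("need N >= 1 non-negative b-values")
        norms = np.linalg.norm(self.directions, axis=1)
        weighted = self.b_values > 50
        if not np.allclose(norms[weighted], 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")

    @property
    def n(self) -> int:
        return len(self.b_values)

    @property
    def b0_mask(self) -> np.ndarray:
        """Images with negligible diffusion weighting (b <= 50 s/mm^2)."""
        return self.b_values <= 50

    def dw_subset(self, Y: np.ndarray) -> np.ndarray:
        """Diffusion-weighted rows of a data array over this scheme.

        Accepts data over all rows (low-b included) or already subset to the
        diffusion-weighted rows.
        """
        Y = np.asarray(Y, dtype=float)
        n_dw = int((~self.b0_mask).sum())
        if Y.shape[-1] == self.n:
            return Y[..., ~self.b0_mask]
        if Y.shape[-1] == n_dw:
            return Y
        raise ValueError(
            f"data has {Y.shape[-1]} rows; expected {self.n} or {n_dw}"
        )

    def shell(self) -> "AcquisitionScheme":
        """The diffusion-weighted subset; raises if it spans multiple shells."""
        dw = ~self.b0_mask
        bs = np.unique(np.round(self.b_values[dw], 6))
        if len(bs) != 1:
            raise NotImplementedError(
                f"multi-shell schemes are not supported (b-values {bs})"
            )
        return AcquisitionScheme(self.directions[dw], self.b_values[dw])


@dataclass
class MicroFOD2D:
    """Normalised symmetric 2D FOD histogram over in-plane angle [-pi/2, pi/2).

    Bins are floored at 2e-16 (so KL terms are finite) and sum to 1.
    """

    bin_centres: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centres = np.asarray(self.bin_centres, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.bin_centres.shape != self.probs.shape or self.bin_centres.ndim != 1:
            raise ValueError("bin_centres and probs must be matching 1D arrays")
        if np.any(self.probs < FLOOR):
            raise ValueError(f"all bins must be >= {FLOOR}")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.probs)

    @classmethod
    def from_masses(cls, masses: np.ndarray, n_bins: int | None = None) -> "MicroFOD2D":
        """Floor raw non-negative bin masses and normalise to a distribution."""
        masses = np.asarray(masses, dtype=float)
        if n_bins is None:
            n_bins = len(masses)
        total = masses.sum()
        probs = masses / total if total > 0 else np.full(n_bins, 1.0 / n_bins)
        probs = np.maximum(probs, FLOOR)
        probs = probs / probs.sum()
        # renormalising can push floored bins a hair under the floor again;
        # re-applying it perturbs the sum by < n_bins * FLOOR, within tolerance
        probs = np.maximum(probs, FLOOR)
        return cls(bin_centres=bin_centres(n_bins), probs=probs)

    def same_binning(self, other: "MicroFOD2D") -> bool:
        return self.n_bins == other.n_bins and np.allclose(
            self.bin_centres, other.bin_centres
        )


def bin_centres(n_bins: int) -> np.ndarray:
    """Centres of ``n_bins`` equal bins partitioning [-pi/2, pi/2)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    width = np.pi / n_bins
    return -np.pi / 2 + (np.arange(n_bins) + 0.5) * width


def fold_azimuth(theta: np.ndarray) -> np.ndarray:
    """Fold angles onto [-pi/2, pi/2) by antipodal (axial) symmetry."""
    return np.mod(np.asarray(theta) + np.pi / 2, np.pi) - np.pi / 2


def azimuth_bin_index(theta: np.ndarray, n_bins: int) -> np.ndarray:
    folded = fold_azimuth(theta)
    idx = np.floor((folded + np.pi / 2) / np.pi * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def frf_signal(frf: ResponseFunction, cos_angle) -> np.ndarray:
    """Tensor FRF attenuation at angle(s) gamma from the fibre, via cos(gamma)."""
    c = np.asarray(cos_angle, dtype=float)
    if np.any(np.abs(c) > 1 + 1e-12):
        raise ValueError("cos_angle must lie in [-1, 1]")
    b = frf.b_value * 1e-3  # s/mm^2 -> ms/um^2
    return np.exp(-b * (frf.d_radial + (frf.d_axial - frf.d_radial) * c**2))


def frf_rotational_harmonics(
    frf: ResponseFunction, lmax: int, n_quad: int = 64
) -> RotationalHarmonics:
    """Funk-Hecke multipliers of the FRF profile (the Eq-1 kernel in SH form)."""
    rh = kernel_rh(lambda t: frf_signal(frf, t), lmax, n_quad=n_quad)
    rh.b_value = frf.b_value
    return rh


def plane_basis(plane_normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (e1, e2) with e2 = normal x e1.

    For the default normal (0,0,1) this returns the x and y axes, so in-plane
    azimuth follows the usual atan2(y, x) convention.
    """
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / nn
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.99:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


class SphereWorkspace:
    """Precomputed SH machinery on a fixed dense sphere.

    Bundles the basis matrix B, its pseudoinverse (least-squares analysis
    operator) and cached azimuth-bin assignments, so repeated forward-model
    evaluations (MCMC, optimisation) avoid rebuilding them.
    """

    def __init__(self, sphere: DenseSphere | None = None, lmax: int = 6):
        self.sphere = sphere if sphere is not None else default_sphere()
        self.lmax = lmax
        self.B = sh_basis_matrix(lmax, self.sphere.directions)
        self.pinvB = np.linalg.pinv(self.B)
        self._bin_cache: dict[tuple, np.ndarray] = {}

    def amplitudes(self, fod: SHCoefficients) -> np.ndarray:
        if fod.lmax != self.lmax:
            raise ValueError("FOD order does not match workspace")
        return self.B @ fod.coeffs

    def analyse(self, amplitudes: np.ndarray) -> SHCoefficients:
        """Least-squares SH coefficients of point amplitudes on the sphere."""
        return SHCoefficients(self.lmax, self.pinvB @ amplitudes)

    def clip(self, fod: SHCoefficients) -> tuple[np.ndarray, float]:
        amps = self.amplitudes(fod)
        neg = np.minimum(amps, 0.0)
        e_neg = float(-(self.sphere.weights * neg).sum())
        return amps - neg, e_neg

    def wedge_matrix(self, plane_normal, n_bins: int) -> np.ndarray:
        """Exact azimuthal-marginalisation operator for band-limited FODs.

        Row i holds the integrals of each SH basis function over the spherical
        wedge whose (folded) in-plane azimuth falls in bin i, so
        ``wedge_matrix @ coeffs`` is the bin mass of the projected FOD. The
        wedge integrals use Gauss-Legendre quadrature in both the out-of-plane
        sine and the within-bin azimuth, exact for the band-limited basis.
        """
        key = (tuple(np.round(np.asarray(plane_normal, float), 12)), n_bins)
        if key not in self._bin_cache:
            e1, e2 = plane_basis(plane_normal)
            width = np.pi / n_bins
            # v(theta, s) = sqrt(1-s^2)(cos(theta) e1 + sin(theta) e2) + s n,
            # with dOmega = ds dtheta; s = sine of the out-of-plane angle
            ts, ws_ = np.polynomial.legendre.leggauss(48)
            tq, wq = np.polynomial.legendre.leggauss(6)
            # theta nodes for every bin at once; the antipodal wedge theta+pi
            # contributes identically for even-order harmonics, hence factor 2
            theta0 = -np.pi / 2 + np.arange(n_bins) * width
            theta = theta0[:, None] + (tq[None, :] + 1) * (width / 2)
            n_vec = np.cross(e1, e2)
            r = np.sqrt(1 - ts**2)
            v = (
                r[None, None, :, None]
                * (
                    np.cos(theta)[..., None, None] * e1
                    + np.sin(theta)[..., None, None] * e2
                )
                + ts[None, None, :, None] * n_vec
            )  # (n_bins, n_tq, n_ts, 3)
            flat = v.reshape(-1, 3)
            flat /= np.linalg.norm(flat, axis=1, keepdims=True)
            Bf = sh_basis_matrix(self.lmax, flat)
            wgt = (wq[:, None] * (width / 2) * ws_[None, :]).ravel()
            A = 2.0 * np.einsum(
                "bqn,q->bn",
                Bf.reshape(n_bins, len(wq) * len(ts), -1),
                wgt,
            )
            self._bin_cache[key] = A
        return self._bin_cache[key]

    def project_2d(
        self,
        clipped_fod: SHCoefficients | np.ndarray,
        plane_normal=(0, 0, 1),
        n_bins: int = 180,
    ) -> MicroFOD2D:
        """2D projection of a (clipped, band-limited) FOD given by SH coeffs."""
        coeffs = (
            clipped_fod.coeffs
            if isinstance(clipped_fod, SHCoefficients)
            else np.asarray(clipped_fod, dtype=float)
        )
        masses = self.wedge_matrix(plane_normal, n_bins) @ coeffs
        return MicroFOD2D.from_masses(np.maximum(masses, 0.0), n_bins)


def clip_negative(
    fod: SHCoefficients, sphere: DenseSphere
) -> tuple[np.ndarray, float]:
    """Clip negative FOD lobes on the sphere grid.

    Returns the non-negative amplitudes and E_neg, the quadrature-weighted sum
    of negative-lobe magnitudes (resolution independent; zero iff the FOD is
    non-negative on the grid).
    """
    amps = eval_sh(fod, sphere.directions)
    neg = np.minimum(amps, 0.0)
    e_neg = float(-(sphere.weights * neg).sum())
    return amps - neg, e_neg


def project_fod_2d(
    fod: SHCoefficients,
    sphere: DenseSphere,
    plane_normal=(0.0, 0.0, 1.0),
    n_bins: int = 180,
) -> MicroFOD2D:
    """Project the (negativity-clipped) 3D FOD onto a 2D plane histogram.

    The FOD is clipped to be non-negative on the dense sphere, re-expanded in
    SH, and its azimuthal marginal -- the solid-angle integral over each
    in-plane-angle wedge, folded to [-pi/2, pi/2) by antipodal symmetry -- is
    computed exactly for the band-limited expansion, then floored and
    renormalised. This matches a histogram of in-plane-projected fibre
    orientations drawn from the FOD.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    plane_basis(plane_normal)  # validates the normal
    ws = SphereWorkspace(sphere, fod.lmax)
    amps, _ = ws.clip(fod)
    return ws.project_2d(ws.analyse(amps), plane_normal, n_bins)


def predict_signal(
    fod: SHCoefficients,
    frf: ResponseFunction,
    scheme: AcquisitionScheme,
    sphere: DenseSphere | None = None,
    workspace: SphereWorkspace | None = None,
) -> np.ndarray:
    """Predicted attenuation along each scheme direction.

    The FOD is clipped to be non-negative on the dense sphere (negative peaks
    contribute to neither the signal nor the 2D projection), re-expanded in SH,
    and convolved with the FRF kernel by per-order scaling. The scheme may
    contain at most one diffusion-weighted shell; low-b rows (b <= 50 s/mm^2),
    if present, are predicted with the same tensor kernel at their own b-value
    (their attenuation is essentially the total FOD mass, which anchors the
    otherwise arbitrary FOD scale).
    """
    scheme.shell()  # validates the single-shell restriction
    if workspace is None:
        sphere = sphere if sphere is not None else default_sphere()
        workspace = SphereWorkspace(sphere, fod.lmax)
    amps, _ = workspace.clip(fod)
    c_clip = workspace.analyse(amps)
    out = np.empty(scheme.n)
    for b in np.unique(scheme.b_values):
        rows = scheme.b_values == b
        rh = frf_rotational_harmonics(
            ResponseFunction(frf.d_axial, frf.d_radial, b), fod.lmax
        )
        out[rows] = convolve(c_clip, rh, scheme.directions[rows])
    return out
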