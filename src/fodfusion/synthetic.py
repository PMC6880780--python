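"""Simulators for validation: Watson-dispersed fibre populations, noisy dMRI
attenuations, and synthetic 2D histology FODs.

The simulated study conditions are a single dispersed fibre population with
orientation dispersion index ODI = 0.25 (Watson concentration kappa ~ 2.414),
d_axial = 0.2 um^2/ms, d_radial = 0.1 um^2/ms, measured over 120 gradient
directions at b = 5000 s/mm^2 with Gaussian noise at SNR = 15 (S0 = 100).
Synthetic histology draws 1400 x 1400 fibre orientations from the same Watson
distribution, projects them into the histology plane and histograms the
in-plane angles; no noise is added to the histology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .forward import (
    AcquisitionScheme,
    MicroFOD2D,
    SphereWorkspace,
    ResponseFunction,
    plane_basis,
    azimuth_bin_index,
    frf_rotational_harmonics,
)
from .spherical import SHCoefficients, convolve

__all__ = [
    "GROUND_TRUTH",
    "WatsonParams",
    "NoiseModel",
    "odi_from_kappa",
    "kappa_from_odi",
    "watson_density",
    "sample_watson",
    "watson_sh",
    "simulate_dmri",
    "simulate_histology",
    "rotate_micro_fod",
    "make_scheme",
]

#: Fixed simulation ground truth used throughout the validation experiments.
GROUND_TRUTH = {
    "odi": 0.25,
    "d_axial": 0.2,  # um^2/ms
    "d_radial": 0.1,  # um^2/ms
    "snr": 15.0,
    "s0": 100.0,
    "b_value": 5000.0,  # s/mm^2
    "n_directions": 120,
    "n_histology_samples": 1400 * 1400,
}


def odi_from_kappa(kappa: float) -> float:
    """Orientation dispersion index ODI = (2/pi) * arctan(1/kappa)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return float(2.0 / np.pi * np.arctan(1.0 / kappa))


def kappa_from_odi(odi: float) -> float:
    """Watson concentration from the dispersion index; inverse of odi_from_kappa."""
    if not 0 < odi < 1:
        raise ValueError("ODI must lie in (0, 1)")
    return float(1.0 / np.tan(odi * np.pi / 2.0))


@dataclass
class WatsonParams:
    """Watson fibre population: mean axis by azimuth/inclination, concentration.

    ``theta`` is the in-plane azimuth and ``phi`` the inclination out of the
    histology (x-y) plane, both in radians; phi = 0 is an in-plane fibre.
    """

    theta: float = 0.0
    phi: float = 0.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @classmethod
    def from_odi(cls, odi: float, theta: float = 0.0, phi: float = 0.0):
        return cls(theta=theta, phi=phi, kappa=kappa_from_odi(odi))

    @property
    def odi(self) -> float:
        return odi_from_kappa(self.kappa)

    @property
    def mu(self) -> np.ndarray:
        """Unit mean axis."""
        return np.array(
            [
                np.cos(self.phi) * np.cos(self.theta),
                np.cos(self.phi) * np.sin(self.theta),
                np.sin(self.phi),
            ]
        )


@dataclass
class NoiseModel:
    """Gaussian noise on the signal: SNR = S0 / sigma_noise, so the noise SD on
    the attenuation scale (signal / S0) is 1/SNR. SNR = inf means noiseless."""

    snr: float = 15.0
    s0: float = 100.0

    @property
    def sigma_noise(self) -> float:
        return self.s0 / self.snr

    @property
    def sigma_attenuation(self) -> float:
        return 1.0 / self.snr


_GL_T, _GL_W = leggauss(200)


def _watson_norm_shifted(kappa: float) -> float:
    """Peak-referenced normaliser 2*pi * int exp(kappa (t^2 - 1)) dt.

    Equals Z * exp(-kappa) with Z the surface integral of exp(kappa (mu.v)^2);
    the shift keeps the quadrature overflow-free for large concentrations.
    """
    return float(2 * np.pi * np.sum(_GL_W * np.exp(kappa * (_GL_T**2 - 1.0))))


def watson_density(w: WatsonParams, dirs: np.ndarray) -> np.ndarray:
    """Normalised Watson density exp(kappa (mu.v)^2) / Z at unit directions."""
    t2 = (np.atleast_2d(dirs) @ w.mu) ** 2
    return np.exp(w.kappa * (t2 - 1.0)) / _watson_norm_shifted(w.kappa)


def sample_watson(w: WatsonParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` axes from the Watson distribution by rejection sampling.

    Uniform proposals on the sphere are accepted when U(0,1) <= P/Pmax, the
    density scaled by its maximum (attained on the mean axis). For extreme
    concentrations where acceptance falls below 1e-4 an exact inverse-CDF
    sampler on cos(angle-from-axis) is used instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # acceptance probability = Z / (4*pi*exp(kappa))
    acc = _watson_norm_shifted(w.kappa) / (4 * np.pi)
    if acc < 1e-4:
        warnings.warn(
            f"rejection acceptance {acc:.2e} too low (kappa={w.kappa:.3g}); "
            "switching to inverse-CDF sampling"
        )
        return _sample_watson_invcdf(w, n, rng)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(int((n - got) / acc * 1.1), 1000)
        v = rng.standard_normal((m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t2 = (v @ w.mu) ** 2
        keep = rng.uniform(size=m) <= np.exp(w.kappa * (t2 - 1.0))
        v = v[keep]
        take = min(len(v), n - got)
        out[got : got + take] = v[:take]
        got += take
    return out


def _sample_watson_invcdf(w: WatsonParams, n: int, rng) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, 200_001)
    pdf = np.exp(w.kappa * (t**2 - 1.0))  # scaled; normalisation cancels in CDF
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
    cdf /= cdf[-1]
    ct = np.interp(rng.uniform(size=n), cdf, t)
    st = np.sqrt(np.clip(1 - ct**2, 0, 1))
    psi = rng.uniform(0, 2 * np.pi, size=n)
    # frame with e3 = mean axis
    e3 = w.mu
    e1, e2 = plane_basis(e3)
    return (
        st[:, None] * np.cos(psi)[:, None] * e1
        + st[:, None] * np.sin(psi)[:, None] * e2
        + ct[:, None] * e3
    )


def watson_sh(
    w: WatsonParams, workspace: SphereWorkspace | None = None
) -> SHCoefficients:
    """Band-limited SH representation of the Watson FOD (least-squares
    projection of the analytic density onto the workspace's even-order basis)."""
    if workspace is None:
        workspace = SphereWorkspace()
    dens = watson_density(w, workspace.sphere.directions)
    return workspace.analyse(dens)


def simulate_dmri(
    w: WatsonParams,
    frf: ResponseFunction,
    scheme: AcquisitionScheme,
    noise: NoiseModel,
    seed,
    workspace: SphereWorkspace | None = None,
) -> np.ndarray:
    """Noisy attenuations: Watson FOD (band-limited, negativity-clipped)
    convolved with the FRF kernel, plus zero-mean Gaussian noise of SD 1/SNR."""
    if workspace is None:
        workspace = SphereWorkspace()
    fod = watson_sh(w, workspace)
    amps, _ = workspace.clip(fod)
    c_clip = workspace.analyse(amps)
    scheme.shell()  # validates the single-shell restriction
    s = np.empty(scheme.n)
    for b in np.unique(scheme.b_values):
        rows = scheme.b_values == b
        rh = frf_rotational_harmonics(
            ResponseFunction(frf.d_axial, frf.d_radial, b), workspace.lmax
        )
        s[rows] = convolve(c_clip, rh, scheme.directions[rows])
    if np.isinf(noise.snr):
        return s
    rng = np.random.default_rng(seed)
    return s + rng.normal(0.0, noise.sigma_attenuation, size=s.shape)


def simulate_histology(
    w: WatsonParams,
    n: int = GROUND_TRUTH["n_histology_samples"],
    n_bins: int = 180,
    seed=0,
    plane_normal=(0.0, 0.0, 1.0),
) -> MicroFOD2D:
    """Synthetic microscopy 2D FOD: Watson axes projected into the plane and
    histogrammed over the folded in-plane angle. No noise beyond sampling."""
    v = sample_watson(w, n, seed)
    e1, e2 = plane_basis(plane_normal)
    theta = np.arctan2(v @ e2, v @ e1)
    idx = azimuth_bin_index(theta, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return MicroFOD2D.from_masses(counts, n_bins)


def rotate_micro_fod(f: MicroFOD2D, delta_theta: float) -> MicroFOD2D:
    """Circularly shift a 2D FOD histogram by ``delta_theta`` radians
    (misregistration injection). Non-multiples of the bin width are rounded to
    the nearest bin with a warning."""
    width = np.pi / f.n_bins
    shift = delta_theta / width
    k = int(np.round(shift))
    if abs(shift - k) > 1e-9:
        warnings.warn(
            f"rotation {delta_theta:.4g} rad is not a multiple of the bin width; "
            f"using nearest shift of {k} bins"
        )
    return MicroFOD2D(bin_centres=f.bin_centres, probs=np.roll(f.probs, k))


def make_scheme(
    n_dirs: int = GROUND_TRUTH["n_directions"],
    b_value: float = GROUND_TRUTH["b_value"],
    n_b0: int = 0,
    b0_value: float = 8.0,
) -> AcquisitionScheme:
    """Single-shell gradient table with a Fibonacci-hemisphere direction set
    (quasi-uniform coverage, as antipodal symmetry makes a hemisphere
    sufficient). Optional low-b images are prepended."""
    i = np.arange(n_dirs)
    z = (i + 0.5) / n_dirs
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * i
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    bvals = np.full(n_dirs, float(b_value))
    if n_b0 > 0:
        dirs = np.vstack([np.tile([0.0, 0.0, 1.0], (n_b0, 1)), dirs])
        bvals = np.concatenate([np.full(n_b0, float(b0_value)), bvals])
    return AcquisitionScheme(directions=dirs, b_values=bvals)
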