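"""Real even-order spherical harmonics, dense sphere sampling and SH-domain convolution.

The fibre orientation distribution (FOD) is antipodally symmetric, so only
even-order harmonics are used. The basis is real and orthonormal on the
sphere, ordered by l ascending and, within each l, m = -l..l:

    Y_{l,m} = sqrt(2) * (-1)^m * Im(Y_l^{|m|})   for m < 0
    Y_{l,0} = Y_l^0 (real)
    Y_{l,m} = sqrt(2) * (-1)^m * Re(Y_l^m)       for m > 0

With this convention the spherical convolution of an FOD with an axially
symmetric kernel h(cos gamma) is, by the Funk-Hecke theorem, a per-order
scaling of the FOD coefficients by f_l = 2*pi * int_{-1}^{1} h(t) P_l(t) dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "SHCoefficients",
    "DenseSphere",
    "RotationalHarmonics",
    "sh_basis_size",
    "sh_degrees",
    "sh_basis_matrix",
    "eval_sh",
    "kernel_rh",
    "convolve",
    "dense_sphere",
    "save_sh",
    "load_sh",
]


def sh_basis_size(lmax: int) -> int:
    """Number of real even-order SH coefficients up to order ``lmax``.

    R(lmax) = (lmax/2 + 1)(lmax + 1); R(6) = 28.
    """
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return (lmax // 2 + 1) * (lmax + 1)


def sh_degrees(lmax: int) -> np.ndarray:
    """Degree l of each coefficient in the (l ascending, m = -l..l) ordering."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, lmax + 1, 2)]
    )


@dataclass
class SHCoefficients:
    """Real even-order SH coefficients of a spherical function (an FOD).

    lmax 6 gives the 28-coefficient representation used by the joint model.
    """

    lmax: int
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        n = sh_basis_size(self.lmax)
        if self.coeffs.shape != (n,):
            raise ValueError(
                f"expected {n} coefficients for lmax={self.lmax}, "
                f"got shape {self.coeffs.shape}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("SH coefficients must be finite")


@dataclass
class DenseSphere:
    """Dense unit-sphere sampling with equal-area quadrature weights.

    ``directions`` are the vertices of a subdivided icosahedron; ``weights``
    are 4*pi/N each and sum to 4*pi. ``faces`` retains the triangulation so
    vertex adjacency (for FOD peak finding) can be reconstructed.
    """

    directions: np.ndarray
    weights: np.ndarray
    faces: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("sphere directions must be unit vectors")
        if np.any(self.weights < 0):
            raise ValueError("quadrature weights must be non-negative")
        if abs(self.weights.sum() - 4 * np.pi) > 1e-6:
            raise ValueError("quadrature weights must sum to 4*pi")

    @property
    def n(self) -> int:
        return len(self.directions)

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency list of the triangulation (empty if faces unavailable)."""
        if self.faces is None:
            raise ValueError("sphere has no face information")
        adj: list[set[int]] = [set() for _ in range(self.n)]
        for a, b, c in self.faces:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return [np.fromiter(s, dtype=int) for s in adj]


@dataclass
class RotationalHarmonics:
    """Per-order Funk-Hecke multipliers f_l (even l) of an axially symmetric kernel."""

    f_l: np.ndarray  # one entry per even l = 0, 2, ..., lmax
    b_value: float = np.nan

    def __post_init__(self) -> None:
        self.f_l = np.asarray(self.f_l, dtype=float)
        if not np.all(np.isfinite(self.f_l)):
            raise ValueError("rotational harmonics must be finite")

    @property
    def lmax(self) -> int:
        return 2 * (len(self.f_l) - 1)


def _check_unit(dirs: np.ndarray) -> np.ndarray:
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    if dirs.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    if not np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-8):
        raise ValueError("directions must be unit vectors")
    return dirs


def sh_basis_matrix(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Design matrix B with B[i, n] = Y_n(dirs[i]) in the canonical ordering."""
    dirs = _check_unit(dirs)
    polar = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    azim = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), polar, azim)
            if m < 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            cols.append(col)
    return np.stack(cols, axis=1)


def eval_sh(c: SHCoefficients, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the SH expansion at unit directions; linear in the coefficients."""
    return sh_basis_matrix(c.lmax, dirs) @ c.coeffs


def kernel_rh(profile, lmax: int, n_quad: int = 64) -> RotationalHarmonics:
    """Funk-Hecke multipliers of an axially symmetric kernel ``profile(cos gamma)``.

    f_l = 2*pi * int_{-1}^{1} profile(t) P_l(t) dt, computed with
    ``n_quad``-node Gauss-Legendre quadrature (exact for polynomial profiles of
    degree < 2*n_quad - lmax). With the orthonormal real basis of this module,
    ``convolve`` then reproduces the direct spherical convolution integral.
    """
    if n_quad < lmax + 1:
        raise ValueError(f"n_quad={n_quad} too small for lmax={lmax}")
    t, w = leggauss(n_quad)
    p = np.asarray(profile(t), dtype=float)
    if p.shape != t.shape:
        p = np.broadcast_to(p, t.shape)
    ls = np.arange(0, lmax + 1, 2)
    f_l = np.array([2 * np.pi * np.sum(w * p * eval_legendre(l, t)) for l in ls])
    return RotationalHarmonics(f_l=f_l)


def convolve(
    fod: SHCoefficients, rh: RotationalHarmonics, scheme_dirs: np.ndarray
) -> np.ndarray:
    """Spherical convolution FOD * kernel evaluated at ``scheme_dirs``.

    Per-order scaling of the FOD coefficients by the kernel's rotational
    harmonics followed by SH evaluation; linear in the FOD.
    """
    if fod.lmax != rh.lmax:
        raise ValueError(f"order mismatch: fod lmax={fod.lmax}, kernel lmax={rh.lmax}")
    scaled = fod.coeffs * rh.f_l[sh_degrees(fod.lmax) // 2]
    return eval_sh(SHCoefficients(fod.lmax, scaled), scheme_dirs)


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return v, f


def dense_sphere(subdivisions: int = 4) -> DenseSphere:
    """Icosahedral sphere tessellation: 10*4^s + 2 vertices (2562 at s=4).

    Equal-area weights 4*pi/N. The default keeps FOD negativity detection
    reliable at lmax = 6.
    """
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}
        verts_list = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint_cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                midpoint_cache[key] = len(verts_list)
                verts_list.append(m)
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=int)
    n = len(verts)
    weights = np.full(n, 4 * np.pi / n)
    return DenseSphere(directions=verts, weights=weights, faces=faces)


def save_sh(path, c: SHCoefficients) -> None:
    """One coefficient per line with its (l, m) label: ``l m value``."""
    degrees = sh_degrees(c.lmax)
    with open(path, "w") as fh:
        fh.write("# l m coefficient (real orthonormal even-order SH)\n")
        i = 0
        for l in range(0, c.lmax + 1, 2):
            for m in range(-l, l + 1):
                fh.write(f"{l} {m} {float(c.coeffs[i])!r}\n")
                i += 1
        assert i == len(degrees)


def load_sh(path) -> SHCoefficients:
    rows = np.loadtxt(path, comments="#", ndmin=2)
    lmax = int(rows[:, 0].max())
    expected_l = sh_degrees(lmax)
    if not np.array_equal(rows[:, 0].astype(int), expected_l):
        raise ValueError("coefficient file does not follow the canonical ordering")
    return SHCoefficients(lmax=lmax, coeffs=rows[:, 2])
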