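"""File-format glue: FSL-dialect gradient tables, NIfTI volumes, 2D FOD CSVs."""

from __future__ import annotations

import numpy as np

from .forward import AcquisitionScheme, MicroFOD2D

__all__ = [
    "read_scheme",
    "write_scheme",
    "load_attenuations",
    "save_nifti",
    "read_micro_fod_csv",
    "write_micro_fod_csv",
]


def read_scheme(bvec_path, bval_path) -> AcquisitionScheme:
    """Read an FSL-dialect gradient table (3xN bvec and 1xN bval text files)."""
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    if bvecs.shape == (3, len(bvals)):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f"bvec shape {bvecs.shape} incompatible with {len(bvals)} b-values"
        )
    # normalise non-zero rows; b~0 rows are conventionally all-zero
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs[nz] /= norms[nz, None]
    bvecs[~nz] = [0.0, 0.0, 1.0]
    return AcquisitionScheme(directions=bvecs, b_values=bvals)


def write_scheme(scheme: AcquisitionScheme, bvec_path, bval_path) -> None:
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.1f")


def load_attenuations(dwi_path, scheme: AcquisitionScheme) -> np.ndarray:
    """Load a 4D DWI NIfTI and normalise to attenuations by the mean b~0 image.

    Returns an array of shape (X, Y, Z, N_dw) over the diffusion-weighted
    directions only; the low-b images are consumed by the normalisation.
    """
    import nibabel as nib

    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.shape[-1] != scheme.n:
        raise ValueError(
            f"volume has {data.shape[-1]} frames but the scheme lists {scheme.n}"
        )
    b0 = scheme.b0_mask
    if b0.any():
        s0 = data[..., b0].mean(axis=-1, keepdims=True)
        s0 = np.where(s0 > 0, s0, 1.0)
        return data[..., ~b0] / s0
    return data


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    import nibabel as nib

    affine = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_micro_fod_csv(path, fod: MicroFOD2D) -> None:
    """CSV with columns bin_centre_rad, prob."""
    arr = np.column_stack([fod.bin_centres, fod.probs])
    np.savetxt(path, arr, delimiter=",", header="bin_centre_rad,prob", comments="")


def read_micro_fod_csv(path) -> MicroFOD2D:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return MicroFOD2D(bin_centres=arr[:, 0], probs=arr[:, 1])
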