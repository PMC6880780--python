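"""Forward model: FRF profile, signal prediction, clipping, 2D projection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fodfusion.forward import (
    AcquisitionScheme,
    MicroFOD2D,
    ResponseFunction,
    clip_negative,
    fold_azimuth,
    frf_signal,
    predict_signal,
    project_fod_2d,
)
from fodfusion.spherical import SHCoefficients, eval_sh
from fodfusion.synthetic import (
    WatsonParams,
    make_scheme,
    sample_watson,
    watson_sh,
)


class TestFrfSignal:
    def test_no_diffusion_weighting(self):
        frf = ResponseFunction(0.0, 0.0, 5000.0)
        assert frf_signal(frf, 0.3) == pytest.approx(1.0)

    def test_parallel_attenuation(self):
        # b * d_axial = 5 ms/um^2 * 0.2 um^2/ms = 1
        frf = ResponseFunction(0.2, 0.0, 5000.0)
        assert frf_signal(frf, 1.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_perpendicular_attenuation(self):
        frf = ResponseFunction(0.2, 0.1, 5000.0)
        assert frf_signal(frf, 0.0) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_cos_out_of_range(self):
        with pytest.raises(ValueError):
            frf_signal(ResponseFunction(0.2, 0.1, 5000.0), 1.5)

    def test_invalid_diffusivities(self):
        with pytest.raises(ValueError):
            ResponseFunction(0.1, 0.2, 5000.0)
        with pytest.raises(ValueError):
            ResponseFunction(0.2, -0.1, 5000.0)


class TestPredictSignal:
    def test_isotropic(self, workspace, scheme120):
        c = np.zeros(28)
        c[0] = 1.0 / np.sqrt(4 * np.pi)  # unit-mass isotropic FOD
        frf = ResponseFunction(0.1, 0.1, 5000.0)
        s = predict_signal(SHCoefficients(6, c), frf, scheme120, workspace=workspace)
        assert np.allclose(s, np.exp(-0.5), rtol=1e-6)

    def test_single_fibre_monotone_in_alignment(self, workspace, scheme120):
        w = WatsonParams(kappa=20.0)  # tight in-plane fibre along x
        fod = watson_sh(w, workspace)
        frf = ResponseFunction(0.2, 0.05, 5000.0)
        s = predict_signal(fod, frf, scheme120, workspace=workspace)
        align = np.abs(scheme120.directions @ w.mu)
        # less attenuation (higher signal) perpendicular to the fibre
        assert np.corrcoef(align, s)[0, 1] < -0.9

    def test_scaling_linearity(self, workspace, scheme120):
        w = WatsonParams(kappa=5.0)
        fod = watson_sh(w, workspace)
        frf = ResponseFunction(0.2, 0.1, 5000.0)
        s1 = predict_signal(fod, frf, scheme120, workspace=workspace)
        s2 = predict_signal(
            SHCoefficients(6, 2.5 * fod.coeffs), frf, scheme120, workspace=workspace
        )
        assert np.allclose(s2, 2.5 * s1, atol=1e-12)

    def test_low_b_rows_report_fod_mass(self, workspace):
        scheme = make_scheme(60, 5000.0, n_b0=4)
        c = np.zeros(28)
        c[0] = 1.0 / np.sqrt(4 * np.pi)
        s = predict_signal(
            SHCoefficients(6, c), ResponseFunction(0.2, 0.1, 5000.0), scheme,
            workspace=workspace,
        )
        assert np.allclose(s[scheme.b0_mask], 1.0, atol=2e-3)

    def test_multi_shell_rejected(self, workspace):
        dirs = make_scheme(20, 1000.0).directions
        scheme = AcquisitionScheme(dirs, np.r_[[1000.0] * 10, [3000.0] * 10])
        c = np.zeros(28)
        c[0] = 1.0
        with pytest.raises(NotImplementedError):
            predict_signal(
                SHCoefficients(6, c), ResponseFunction(0.2, 0.1, 1000.0), scheme,
                workspace=workspace,
            )


class TestClipNegative:
    def test_nonnegative_fod_untouched(self, workspace):
        fod = watson_sh(WatsonParams(kappa=2.0), workspace)
        amps, e_neg = clip_negative(fod, workspace.sphere)
        assert e_neg == 0.0
        assert np.allclose(amps, workspace.amplitudes(fod))

    def test_zero_coefficients(self, workspace):
        amps, e_neg = clip_negative(SHCoefficients(6, np.zeros(28)), workspace.sphere)
        assert e_neg == 0.0
        assert np.all(amps == 0.0)

    def test_against_monte_carlo_negative_mass(self, workspace):
        # pure l=2, m=0 component: E_neg must match a Monte-Carlo integral of
        # the negative lobe magnitude
        c = np.zeros(28)
        c[3] = 1.0  # (l=2, m=0)
        fod = SHCoefficients(6, c)
        _, e_neg = clip_negative(fod, workspace.sphere)
        rng = np.random.default_rng(0)
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        amps = eval_sh(fod, v)
        mc = -amps[amps < 0].sum() / len(v) * 4 * np.pi
        assert e_neg == pytest.approx(mc, rel=0.01)


class TestProject2D:
    def test_isotropic_is_uniform(self, workspace):
        c = np.zeros(28)
        c[0] = 1.0
        hist = project_fod_2d(SHCoefficients(6, c), workspace.sphere, n_bins=90)
        assert np.all(np.abs(hist.probs - 1 / 90) < 0.02 / 90)

    def test_inplane_peak_lands_in_right_bin(self, workspace):
        alpha = np.deg2rad(30.0)
        fod = watson_sh(WatsonParams(theta=alpha, kappa=20.0), workspace)
        hist = project_fod_2d(fod, workspace.sphere, n_bins=180)
        assert abs(hist.bin_centres[np.argmax(hist.probs)] - alpha) <= np.deg2rad(1.0)

    def test_matches_projected_watson_sample_histogram(self, workspace):
        # projection of the band-limited Watson FOD vs the direct histogram of
        # 1e6 rejection-sampled fibre orientations, same binning
        w = WatsonParams.from_odi(0.25)
        fod = watson_sh(w, workspace)
        hist = project_fod_2d(fod, workspace.sphere, n_bins=180)
        v = sample_watson(w, 1_000_000, seed=3)
        theta = fold_azimuth(np.arctan2(v[:, 1], v[:, 0]))
        idx = np.floor((theta + np.pi / 2) / np.pi * 180).astype(int).clip(0, 179)
        emp = np.bincount(idx, minlength=180) / len(v)
        tv = 0.5 * np.abs(hist.probs - emp).sum()
        assert tv < 0.02

    def test_inplane_rotation_shifts_histogram(self, workspace):
        base = project_fod_2d(
            watson_sh(WatsonParams(theta=0.0, kappa=5.0), workspace),
            workspace.sphere,
        )
        shift_bins = 25  # 25 degrees
        rotated = project_fod_2d(
            watson_sh(
                WatsonParams(theta=np.deg2rad(shift_bins), kappa=5.0), workspace
            ),
            workspace.sphere,
        )
        tv = 0.5 * np.abs(np.roll(base.probs, shift_bins) - rotated.probs).sum()
        assert tv < 0.05

    def test_zero_plane_normal_rejected(self, workspace):
        c = np.zeros(28)
        c[0] = 1.0
        with pytest.raises(ValueError):
            project_fod_2d(
                SHCoefficients(6, c), workspace.sphere, plane_normal=(0, 0, 0)
            )


class TestMicroFOD2D:
    def test_from_masses_invariants(self):
        masses = np.zeros(180)
        masses[10] = 3.0
        hist = MicroFOD2D.from_masses(masses)
        assert hist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(hist.probs >= 2e-16)

    @given(st.integers(0, 2**31 - 1))
    def test_random_masses_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        masses = np.abs(rng.standard_normal(64)) * rng.integers(0, 2, size=64)
        hist = MicroFOD2D.from_masses(masses)
        assert hist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(hist.probs >= 2e-16)

    def test_fold_azimuth_range(self):
        theta = np.linspace(-7, 7, 1001)
        folded = fold_azimuth(theta)
        assert np.all(folded >= -np.pi / 2) and np.all(folded < np.pi / 2)
        # antipodal identification: folding theta and theta + pi agree
        assert np.allclose(fold_azimuth(theta + np.pi), folded, atol=1e-12)
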