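"""Watson simulators: dispersion index, rejection sampling, noise, histology."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from fodfusion.synthetic import (
    NoiseModel,
    WatsonParams,
    kappa_from_odi,
    make_scheme,
    odi_from_kappa,
    rotate_micro_fod,
    sample_watson,
    simulate_dmri,
    simulate_histology,
)
from fodfusion.forward import ResponseFunction


class TestOdiKappa:
    def test_kappa_one_gives_half(self):
        assert odi_from_kappa(1.0) == pytest.approx(0.5, abs=1e-15)

    def test_quarter_odi_kappa(self):
        assert kappa_from_odi(0.25) == pytest.approx(1 / np.tan(np.pi / 8), rel=1e-12)
        assert kappa_from_odi(0.25) == pytest.approx(2.41421, abs=1e-5)

    def test_limits(self):
        assert odi_from_kappa(1e12) < 1e-9
        assert odi_from_kappa(1e-12) > 1 - 1e-9

    def test_round_trip_grid(self):
        odis = np.linspace(0.005, 0.995, 100)
        back = np.array([odi_from_kappa(kappa_from_odi(o)) for o in odis])
        assert np.allclose(back, odis, atol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_invalid_kappa(self, bad):
        with pytest.raises(ValueError):
            odi_from_kappa(bad)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_odi(self, bad):
        with pytest.raises(ValueError):
            kappa_from_odi(bad)


class TestSampleWatson:
    def test_uniform_limit(self):
        v = sample_watson(WatsonParams(kappa=1e-6), 100_000, seed=0)
        scatter = (v[:, :, None] * v[:, None, :]).mean(axis=0)
        evals = np.linalg.eigvalsh(scatter)
        # scatter matrix of uniform axes is I/3
        assert evals.max() - evals.min() < 0.02

    def test_second_moment_against_quadrature(self):
        w = WatsonParams.from_odi(0.25)
        v = sample_watson(w, 1_000_000, seed=1)
        emp = ((v @ w.mu) ** 2).mean()
        t, wt = leggauss(400)
        dens = np.exp(w.kappa * (t**2 - 1.0))
        expected = np.sum(wt * t**2 * dens) / np.sum(wt * dens)
        assert emp == pytest.approx(expected, abs=0.005)

    def test_seed_determinism(self):
        w = WatsonParams(theta=0.3, phi=0.2, kappa=3.0)
        a = sample_watson(w, 5000, seed=42)
        b = sample_watson(w, 5000, seed=42)
        assert np.array_equal(a, b)

    def test_extreme_concentration_falls_back_to_inverse_cdf(self):
        w = WatsonParams(kappa=kappa_from_odi(1e-4))
        with pytest.warns(UserWarning, match="inverse-CDF"):
            v = sample_watson(w, 2000, seed=2)
        assert np.abs(np.abs(v @ w.mu) - 1).max() < 1e-3


class TestSimulateDmri:
    def test_noiseless_matches_forward_model(self, workspace, scheme120):
        from fodfusion.forward import predict_signal
        from fodfusion.synthetic import watson_sh

        w = WatsonParams.from_odi(0.25)
        frf = ResponseFunction(0.2, 0.1, 5000.0)
        s = simulate_dmri(
            w, frf, scheme120, NoiseModel(snr=np.inf), seed=0, workspace=workspace
        )
        ref = predict_signal(watson_sh(w, workspace), frf, scheme120,
                             workspace=workspace)
        assert np.allclose(s, ref, atol=1e-12)

    def test_noise_level_matches_snr_definition(self, workspace):
        # SNR = S0/sigma_noise = 15 puts SD 1/15 on the attenuation scale
        noise = NoiseModel(snr=15.0)
        assert noise.sigma_noise * noise.snr == pytest.approx(noise.s0, abs=1e-12)
        scheme = make_scheme(100_000, 5000.0)
        w = WatsonParams.from_odi(0.25)
        frf = ResponseFunction(0.2, 0.1, 5000.0)
        noiseless = simulate_dmri(
            w, frf, scheme, NoiseModel(snr=np.inf), seed=0, workspace=workspace
        )
        noisy = simulate_dmri(w, frf, scheme, noise, seed=0, workspace=workspace)
        assert (noisy - noiseless).std() == pytest.approx(1 / 15, rel=0.02)

    def test_seed_determinism(self, workspace, scheme120):
        w = WatsonParams.from_odi(0.25)
        frf = ResponseFunction(0.2, 0.1, 5000.0)
        a = simulate_dmri(w, frf, scheme120, NoiseModel(15), seed=3, workspace=workspace)
        b = simulate_dmri(w, frf, scheme120, NoiseModel(15), seed=3, workspace=workspace)
        assert np.array_equal(a, b)


class TestSimulateHistology:
    def test_tight_inplane_fibre_concentrates(self):
        alpha = np.deg2rad(40.0)
        with pytest.warns(UserWarning, match="inverse-CDF"):
            hist = simulate_histology(
                WatsonParams(theta=alpha, kappa=1e6), n=200_000, seed=0
            )
        k = np.argmin(np.abs(hist.bin_centres - alpha))
        assert hist.probs[max(k - 2, 0) : k + 3].sum() > 0.99

    def test_perpendicular_fibre_is_near_uniform(self):
        hist = simulate_histology(
            WatsonParams.from_odi(0.25, phi=np.pi / 2), n=500_000, seed=1
        )
        tv = 0.5 * np.abs(hist.probs - 1 / hist.n_bins).sum()
        assert tv < 0.05

    def test_single_sample(self):
        hist = simulate_histology(WatsonParams(kappa=2.0), n=1, seed=2)
        assert (hist.probs > 1e-6).sum() == 1


class TestRotate:
    @pytest.fixture()
    def hist(self):
        return simulate_histology(WatsonParams.from_odi(0.25), n=50_000, seed=3)

    def test_zero_is_identity(self, hist):
        assert np.array_equal(rotate_micro_fod(hist, 0.0).probs, hist.probs)

    def test_full_period_is_identity(self, hist):
        assert np.allclose(rotate_micro_fod(hist, np.pi).probs, hist.probs)

    def test_shift_unshift(self, hist):
        delta = np.deg2rad(12.0)
        back = rotate_micro_fod(rotate_micro_fod(hist, delta), -delta)
        assert np.allclose(back.probs, hist.probs)

    def test_non_multiple_warns(self, hist):
        with pytest.warns(UserWarning, match="nearest"):
            rotate_micro_fod(hist, np.deg2rad(1.5))


def test_scheme_construction():
    scheme = make_scheme(120, 5000.0, n_b0=8)
    assert scheme.n == 128
    assert scheme.b0_mask.sum() == 8
    shell = scheme.shell()
    assert shell.n == 120
    assert np.allclose(np.linalg.norm(shell.directions, axis=1), 1.0)
    # quasi-uniform coverage: nearest-neighbour axial angles are tight
    dots = np.abs(shell.directions @ shell.directions.T)
    np.fill_diagonal(dots, 0.0)
    nn = np.degrees(np.arccos(np.clip(dots.max(axis=1), -1, 1)))
    assert nn.max() < 25.0
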