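"""Fitting machinery: simplified Watson likelihood, MCMC, full joint fit."""

import numpy as np
import pytest

from fodfusion.forward import ResponseFunction
from fodfusion.inference import (
    JointCostEvaluator,
    SimplifiedWatsonModel,
    _pack,
    fit_joint,
    sample_watson_posterior,
    watson_loglike,
)
from fodfusion.objective import total_cost
from fodfusion.spherical import SHCoefficients
from fodfusion.synthetic import (
    GROUND_TRUTH,
    NoiseModel,
    WatsonParams,
    make_scheme,
    simulate_dmri,
    simulate_histology,
)


@pytest.fixture(scope="module")
def noiseless(workspace):
    """Noiseless in-plane condition at the fixed ground truth."""
    gt = GROUND_TRUTH
    w = WatsonParams.from_odi(gt["odi"])
    frf = ResponseFunction(gt["d_axial"], gt["d_radial"], gt["b_value"])
    scheme = make_scheme(gt["n_directions"], gt["b_value"])
    Y = simulate_dmri(w, frf, scheme, NoiseModel(snr=np.inf), seed=0,
                      workspace=workspace)
    micro = simulate_histology(w, seed=1)
    return Y, micro, scheme, w


class TestWatsonLoglike:
    def test_truth_is_grid_maximum_on_noiseless_data(self, workspace, noiseless):
        Y, micro, scheme, w = noiseless
        model = SimplifiedWatsonModel(Y, scheme, micro, (0.0, 0.0), 1.0,
                                      sigma=1 / 15, workspace=workspace)
        odis = [0.15, 0.2, 0.25, 0.3, 0.35]
        das = [0.15, 0.2, 0.25]
        drs = [0.05, 0.1, 0.15]
        grid = [
            (o, a, r) for o in odis for a in das for r in drs if a >= r
        ]
        values = [model.log_target(p) for p in grid]
        assert grid[int(np.argmax(values))] == (0.25, 0.2, 0.1)

    def test_lambda_zero_ignores_microscopy(self, workspace, noiseless):
        Y, micro, scheme, _ = noiseless
        other = simulate_histology(WatsonParams.from_odi(0.7), n=10_000, seed=9)
        p = (0.3, 0.22, 0.08)
        a = watson_loglike(Y, scheme, micro, p, lambda_micro=0.0,
                           workspace=workspace)
        b = watson_loglike(Y, scheme, other, p, lambda_micro=0.0,
                           workspace=workspace)
        assert a == b

    def test_heavy_dispersion_scores_below_truth(self, workspace, noiseless):
        Y, micro, scheme, _ = noiseless
        model = SimplifiedWatsonModel(Y, scheme, micro, (0.0, 0.0), 1.0,
                                      sigma=1 / 15, workspace=workspace)
        assert model.log_target((0.95, 0.2, 0.1)) < model.log_target((0.25, 0.2, 0.1))

    def test_constraint_violations_are_rejected(self, workspace, noiseless):
        Y, micro, scheme, _ = noiseless
        model = SimplifiedWatsonModel(Y, scheme, micro, (0.0, 0.0), 1.0,
                                      sigma=1 / 15, workspace=workspace)
        assert model.log_target((0.25, 0.1, 0.2)) == -np.inf  # d_r > d_a
        assert model.log_target((1.2, 0.2, 0.1)) == -np.inf
        assert model.log_target((0.25, 0.2, -0.01)) == -np.inf

    def test_noiseless_optimum_recovers_parameters(self, workspace, noiseless):
        # continuous maximisation, not just the grid: recovery within 5%
        from scipy.optimize import minimize

        Y, micro, scheme, _ = noiseless
        model = SimplifiedWatsonModel(Y, scheme, micro, (0.0, 0.0), 1.0,
                                      sigma=1 / 15, workspace=workspace)
        res = minimize(
            lambda p: -model.log_target(p), [0.5, 0.25, 0.05],
            method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9},
        )
        odi, d_a, d_r = res.x
        assert odi == pytest.approx(0.25, rel=0.05)
        assert d_a == pytest.approx(0.2, rel=0.05)
        assert d_r == pytest.approx(0.1, rel=0.05)


class TestPosteriorSampling:
    def test_seed_determinism(self, workspace, noiseless):
        Y, micro, scheme, _ = noiseless
        kw = dict(lambda_micro=1.0, n_iter=600, seed=21, workspace=workspace)
        a = sample_watson_posterior(Y, scheme, micro, **kw)
        b = sample_watson_posterior(Y, scheme, micro, **kw)
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_samples_respect_constraints(self, posteriors):
        for post in posteriors.values():
            s = post.samples
            assert np.all((s[:, 0] > 0) & (s[:, 0] < 1))
            assert np.all(s[:, 1] >= s[:, 2])
            assert np.all(s[:, 2] >= 0)

    def test_chain_export(self, tmp_path, posteriors):
        import pandas as pd

        path = tmp_path / "chain.csv"
        posteriors[1.0].to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[1:4]) == ["odi", "d_axial", "d_radial"]
        assert len(df) == len(posteriors[1.0].samples)


class TestFitJoint:
    def test_parameter_vector_has_30_entries(self):
        z = _pack(
            ResponseFunction(0.25, 0.05, 5000.0),
            SHCoefficients(6, np.zeros(28)),
        )
        assert len(z) == 30

    def test_evaluator_matches_reference_cost(self, workspace, noiseless):
        Y, micro, scheme, _ = noiseless
        ev = JointCostEvaluator(Y, micro, scheme, 1.0, 1e-3, workspace)
        rng = np.random.default_rng(4)
        for _ in range(3):
            c = rng.standard_normal(28) * 0.1
            c[0] = abs(c[0]) + 0.2
            d_r, d_a = sorted(rng.uniform(0.02, 0.3, size=2))
            ref = total_cost(
                Y, micro, ResponseFunction(d_a, d_r, 5000.0),
                SHCoefficients(6, c), scheme, 1.0, 1e-3, workspace=workspace,
            )
            got = ev.cost(d_a, d_r, c)
            assert got.E == pytest.approx(ref.E, rel=1e-12)
            assert got.E_micro == pytest.approx(ref.E_micro, rel=1e-12)

    def test_descent_from_init_without_regularisers(self, workspace, noiseless):
        Y, _, scheme, _ = noiseless
        init_frf = ResponseFunction(0.25, 0.05, 5000.0)
        c0 = np.zeros(28)
        c0[0] = 1.0 / np.sqrt(4 * np.pi)
        init_fod = SHCoefficients(6, c0)
        e_init = total_cost(
            Y, None, init_frf, init_fod, scheme, 0.0, 0.0, workspace=workspace
        ).E_diff
        fit = fit_joint(
            Y, None, scheme, 0.0, 0.0, init_frf=init_frf, init_fod=init_fod,
            workspace=workspace, n_starts=1, maxiter=100,
        )
        assert fit.cost.E_diff <= e_init
        assert fit.cost.E == min(fit.start_costs)

    def test_noiseless_recovery_with_mass_anchor(self, workspace):
        # the low-b rows pin the FOD scale, making the diffusivities
        # identifiable; recovery on noiseless data is then near-exact
        gt = GROUND_TRUTH
        w = WatsonParams.from_odi(gt["odi"])
        frf = ResponseFunction(gt["d_axial"], gt["d_radial"], gt["b_value"])
        scheme = make_scheme(gt["n_directions"], gt["b_value"], n_b0=8)
        Y = simulate_dmri(w, frf, scheme, NoiseModel(snr=np.inf), seed=0,
                          workspace=workspace)
        micro = simulate_histology(w, seed=1)
        fit = fit_joint(Y, micro, scheme, 1.0, 0.0, workspace=workspace,
                        n_starts=1, maxiter=400)
        assert fit.frf.d_radial == pytest.approx(gt["d_radial"], rel=0.05)
        assert fit.frf.d_axial == pytest.approx(gt["d_axial"], rel=0.05)
        assert fit.frf.d_axial >= fit.frf.d_radial >= 0.0
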