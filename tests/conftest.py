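import pytest
from hypothesis import settings

from fodfusion.forward import SphereWorkspace
from fodfusion.synthetic import make_scheme
from fodfusion.workbench import ExperimentConfig, simulate_condition

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def workspace() -> SphereWorkspace:
    """Shared lmax=6 workspace on the default 2562-point sphere."""
    return SphereWorkspace()


@pytest.fixture(scope="session")
def scheme120():
    """The validation acquisition: 120 directions at b = 5000 s/mm^2."""
    return make_scheme(120, 5000.0)


@pytest.fixture(scope="session")
def config() -> ExperimentConfig:
    return ExperimentConfig(seed=7, n_iter=12_000)


@pytest.fixture(scope="session")
def inplane_condition(config, workspace):
    """Simulated in-plane single-fibre condition at the fixed ground truth."""
    Y, micro, scheme, w, frf = simulate_condition(config, 0.0, workspace=workspace)
    return {"Y": Y, "micro": micro, "scheme": scheme, "watson": w, "frf": frf}


@pytest.fixture(scope="session")
def posteriors(config, workspace, inplane_condition):
    """MCMC posteriors at lambda_micro = 0 and 1 on the same data."""
    from fodfusion.inference import sample_watson_posterior

    cond = inplane_condition
    out = {}
    for lam in (0.0, 1.0):
        out[lam] = sample_watson_posterior(
            cond["Y"], cond["scheme"], cond["micro"], lambda_micro=lam,
            n_iter=config.n_iter, seed=config.seed + 11,
            fixed_peak=(cond["watson"].theta, cond["watson"].phi),
            sigma=1.0 / config.ground_truth["snr"], workspace=workspace,
        )
    return out
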