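import numpy as np
import pytest

from cocpd.model import Endpoint, OperationalParams, TrialArm, operational_response
from cocpd.simulate import SynthDesign, generate_arms, published_pi_params


@pytest.fixture
def pi_params() -> OperationalParams:
    """Published Pearl-Index operational parameter set."""
    return published_pi_params()


@pytest.fixture
def noiseless_arms(pi_params):
    """Arms whose observations sit exactly on the model curve."""
    arms = []
    for drug in pi_params.drugs:
        for k, x in enumerate(np.linspace(2.0, 5.0, 12)):
            cavg = 10.0**x * {"LNG": 312.45, "DRSP": 366.49}[drug] / 1e6
            arms.append(TrialArm(
                study_id="exact", arm_id=f"{drug}-{k}", drug_id=drug,
                dose_ug=0.0, ee_dose_ug=0.0, endpoint=Endpoint.PI,
                observed=float(operational_response(cavg, drug, pi_params)),
                n_subjects=200, cavg=cavg,
            ))
    return arms


@pytest.fixture
def noisy_arms(pi_params):
    """One seeded synthetic dataset at the published parameters."""
    grid = np.linspace(1.8, 5.2, 20)
    design = SynthDesign(
        true_params=pi_params,
        exposure_grid={d: grid for d in pi_params.drugs},
        n_per_arm=500,
        seed=42,
    )
    return generate_arms(design)
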