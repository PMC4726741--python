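import numpy as np
import pytest

import radstress as rs


@pytest.fixture(scope="session")
def m1_params() -> rs.ParameterSet:
    """Reported best-fit coefficients of the killing+suppression law M1,
    completed with the baseline proliferation component g = 0.1 h^-1."""
    return rs.ParameterSet(m=2.11e-3, g=0.1, q=0.599, k=5.78e-4, delta=4.78e-2)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free synthetic steady-state data generated from M1."""
    design = rs.ChemostatDesign(noise_cv=0.0, seed=0)
    dataset, truth = rs.generate_chemostat_dataset(design)
    return dataset, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset):
    dataset, _ = noiseless_dataset
    config = rs.FitConfig(error_model="relative_cv", cv=0.05)
    return rs.ChemostatGrowthModel(dataset, "M1", config).fit(seed=1)


def random_params_for(model: rs.GrowthModel, rng: np.random.Generator) -> rs.ParameterSet:
    """Random admissible parameters on the scales typical of each coefficient."""
    scales = {"m": 2e-3, "g": 0.2, "q": 0.6, "k": 1e-3, "delta": 0.05,
              "mu": 0.02, "sigma": 1e-4}
    values = {
        name: float(scales[name] * rng.uniform(0.2, 2.0))
        for name in model.free_parameters
    }
    return rs.ParameterSet.from_dict(values)
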