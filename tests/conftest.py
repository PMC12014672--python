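import numpy as np
import pytest

import sigwash as sw


@pytest.fixture(scope="session")
def canonical_params() -> sw.SigmoidParams:
    """Well-separated rise/decay phases on a 60-min stimulation design."""
    return sw.SigmoidParams(I=1.0, a1=0.5, a2=-0.5, t_mid1=15.0, t_mid2=75.0)


@pytest.fixture(scope="session")
def param_grid() -> list[sw.SigmoidParams]:
    """Fixed 20-parameter-set grid spanning the regimes the fit explores."""
    rng = np.random.default_rng(20240915)
    out = []
    for _ in range(20):
        out.append(sw.SigmoidParams(
            I=float(rng.uniform(-2.0, 2.0)),
            a1=float(rng.uniform(0.05, 0.6)),
            a2=float(-rng.uniform(0.05, 0.6)),
            t_mid1=float(rng.uniform(0.0, 60.0)),
            t_mid2=float(rng.uniform(40.0, 120.0)),
        ))
    return out


@pytest.fixture(scope="session")
def small_study() -> sw.StudyDataset:
    """Four-animal mixed-cohort study with default generative settings."""
    return sw.simulate_study(sw.SimulationConfig(n_cohort1=2, n_cohort2=2, seed=7))


@pytest.fixture(scope="session")
def default_study() -> sw.StudyDataset:
    """Full-size study (8 + 15 animals) used by aggregate-level tests."""
    return sw.simulate_study(sw.SimulationConfig(seed=11))
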