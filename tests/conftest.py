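import sys
from pathlib import Path

import numpy as np
import pytest

import unico

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def recovery_study():
    """Reference parameter-recovery study: n=500, m=200, k=3, seed 1."""
    truth = unico.simulate_parametric(n=500, m=200, k=3, seed=1)
    fit = unico.fit(truth.bulk, truth.proportions)
    return truth, fit


@pytest.fixture(scope="session")
def null_study():
    """Large null-phenotype study for calibration: 2000 features x 5 cell
    types = 10,000 marginal tests, with both inference modes."""
    truth = unico.simulate_parametric(n=400, m=2000, k=5, seed=11)
    fit = unico.fit(truth.bulk, truth.proportions)
    rng = np.random.default_rng(123)
    phenotype = rng.standard_normal(400)
    param = unico.test_marginal(
        fit, truth.bulk, truth.proportions, phenotype, mode="parametric"
    )
    asymp = unico.test_marginal(
        fit, truth.bulk, truth.proportions, phenotype, mode="asymptotic"
    )
    return truth, fit, phenotype, param, asymp


@pytest.fixture(scope="session")
def effect_study():
    """Case/control study with a 0.5-unit effect planted in cell type 0."""
    truth = unico.simulate_parametric(
        n=500, m=150, k=3,
        effect_spec={"cell_types": [0], "effect_size": 0.5, "binary": True},
        seed=21,
    )
    fit = unico.fit(truth.bulk, truth.proportions)
    result = unico.test_marginal(
        fit, truth.bulk, truth.proportions, truth.phenotype, mode="parametric"
    )
    return truth, fit, result
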