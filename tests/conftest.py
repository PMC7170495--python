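import numpy as np
import pytest

from dyncross.containers import ExpressionTimeCourse
from dyncross.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def time_grid_24h():
    """The study's sampling design: 14 points over 24 hours."""
    return np.linspace(0.0, 24.0, 14)


@pytest.fixture(scope="session")
def small_study():
    """A small four-condition study with planted cross-talk structure."""
    cfg = SimulationConfig(
        n_genes=300,
        n_dynamic=180,
        n_modules=4,
        n_crosstalk=12,
        n_coactivation=8,
        seed=11,
    )
    return cfg, *simulate_study(cfg)


def make_etc(values, time_grid, condition="CTRL", gene_ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n)]
    return ExpressionTimeCourse(
        gene_ids=gene_ids, condition=condition, time_grid=time_grid, values=values
    )
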