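import numpy as np
import pytest

from synscore import DrugSpec, SimulationSpec, simulate_block

UNIT_CURVE = DrugSpec("A", l=0.0, u=100.0, ec50=1.0, h=1.0)
GRID6 = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0)
GRID8 = tuple(np.concatenate([[0.0], np.geomspace(0.03, 30.0, 7)]))


@pytest.fixture
def bliss_block():
    """Noiseless 2-drug block whose interior is exactly the Bliss null."""
    spec = SimulationSpec(
        drugs=(DrugSpec("A", 0, 100, 1.0, 1.0), DrugSpec("B", 0, 90, 0.5, 1.5)),
        dose_grids=(GRID6, GRID6),
        null_model="bliss",
        seed=1,
    )
    block, truth = simulate_block(spec)
    return block, truth


@pytest.fixture
def noisy_spiked_block():
    """Bliss-null block, noise sd 3, one +30 %inh spike at (3, 2)."""
    spec = SimulationSpec(
        drugs=(DrugSpec("A", 0, 100, 1.0, 1.0), DrugSpec("B", 0, 90, 0.5, 1.5)),
        dose_grids=(GRID6, GRID6),
        null_model="bliss",
        noise_sd=3.0,
        outliers=(((3, 2), 30.0),),
        seed=7,
    )
    block, truth = simulate_block(spec)
    return block, truth
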