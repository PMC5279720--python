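import logging

import numpy as np
import pytest

from rhombosim.params import ForceParams, GeneParams, RunConfig
from rhombosim.scem_mechanics import Tissue, step_mechanics

logging.getLogger("rhombosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def forces() -> ForceParams:
    import dataclasses

    # deterministic variant of the shipped defaults for exact-value checks
    return dataclasses.replace(ForceParams(), element_noise=0.0)


@pytest.fixture(scope="session")
def genes() -> GeneParams:
    return GeneParams()


def make_single_cell(forces: ForceParams, n_e: int = 4, seed: int = 0, scatter: float = 0.4) -> Tissue:
    rng = np.random.default_rng(seed)
    pos = scatter * rng.standard_normal((n_e, 2))
    return Tissue(
        pos=pos,
        cell_of=np.zeros(n_e, dtype=np.int64),
        fate=np.array([1], dtype=np.int8),
        domain=(-100.0, 100.0, -100.0, 100.0),
        time=0.0,
        n_e=n_e,
    )


def relax(tissue: Tissue, forces: ForceParams, n_steps: int = 3000) -> Tissue:
    import dataclasses

    forces = dataclasses.replace(forces, element_noise=0.0)  # noise-off relaxation
    dt = 0.5 * forces.max_stable_dt()
    for _ in range(n_steps):
        step_mechanics(tissue, forces, dt)
    return tissue


@pytest.fixture(scope="session")
def relaxed_cell(forces):
    return relax(make_single_cell(forces), forces)


@pytest.fixture(scope="session")
def shared_comparison_ensembles():
    """Paired 16-replicate S/P/SP ensembles from shared morphogen-patterned
    initial states (used by the model-comparison acceptance checks)."""

    from rhombosim import models

    cfg = RunConfig()
    return models.run_ensemble(cfg, base_seed=11, modes=("S", "P", "SP"), n_replicates=16)
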