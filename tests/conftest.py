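import numpy as np
import pandas as pd
import pytest

from ratioqc import ExpressionStudy, SimulationConfig, StudyDesign, simulate_study


def make_design(groups=("A", "B"), reps=2, batch="B1"):
    rows = [
        {"sample": f"{g}_{r}_{batch}", "group": g, "replicate": r, "batch": batch}
        for g in groups
        for r in range(1, reps + 1)
    ]
    return StudyDesign(pd.DataFrame(rows))


def random_study(rng, n_genes=30, groups=("A", "B", "C"), reps=3, separation=1.0, noise=0.5):
    """Small random study with group-mean separation for SNR tests."""
    design = make_design(groups, reps)
    cols = {}
    for gi, g in enumerate(groups):
        for r in range(1, reps + 1):
            cols[f"{g}_{r}_B1"] = rng.normal(gi * separation, noise, n_genes)
    matrix = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return matrix[design.samples], design


@pytest.fixture(scope="session")
def quartet_batch():
    """One standard 4-group x 3-replicate synthetic batch (default conditions)."""
    return simulate_study(SimulationConfig(n_genes=500, seed=101)).batches[0]


@pytest.fixture(scope="session")
def multibatch_study():
    """Eight-batch synthetic study under default conditions."""
    return simulate_study(SimulationConfig(n_genes=300, n_batches=8, seed=202))


@pytest.fixture
def small_design():
    return make_design(groups=("A", "B"), reps=2)
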