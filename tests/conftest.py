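"""Shared fixtures: a trained classifier and a planted recovery experiment.

Training and the end-to-end pipeline run once per session; individual tests
inspect different aspects of the same artifacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from dipms.complexes import PipelineConfig, run_pipeline
from dipms.model import ModelConfig, train_model
from dipms.simulate import (
    ComplexSpec,
    SimulationConfig,
    default_training_configs,
    make_training_corpus,
    simulate_experiment,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def corpus():
    """Balanced labeled corpus from the standard mixed training configs."""
    X, y, pairs, provenance = make_training_corpus(default_training_configs(1), seed=1)
    return {"X": X, "y": y, "pairs": pairs, "provenance": provenance}


@pytest.fixture(scope="session")
def trained_model(corpus):
    return train_model(corpus["X"], corpus["y"], ModelConfig(seed=1), corpus_id="session")


def planted_experiment(seed: int = 7):
    """A hexamer plus two subcomplexes sharing a subunit, over background
    assemblies and contaminants: the standard recovery scenario."""
    rng = np.random.default_rng(seed)
    planted = [
        ComplexSpec("hexamer", [f"H{i}" for i in range(6)], apex=12, sigma=2.0,
                    stoichiometry={"H0": 2.0}),
        ComplexSpec("subA", ["S0", "S1", "S2", "SH"], apex=36, sigma=2.0),
        ComplexSpec("subB", ["S3", "S4", "S5", "SH"], apex=60, sigma=2.0),
    ]
    for k, apex in enumerate([20, 28, 44, 52, 68, 76]):
        size = int(rng.integers(3, 6))
        planted.append(
            ComplexSpec(f"bg{k}", [f"B{k}{i}" for i in range(size)], apex=apex, sigma=2.0)
        )
    return SimulationConfig(
        n_fractions=90, complexes=planted, n_contaminants=10, seed=seed
    )


@pytest.fixture(scope="session")
def recovery_run(trained_model):
    """Full pipeline output on the planted recovery experiment."""
    config = planted_experiment(seed=7)
    tables, truth = simulate_experiment(config)
    result = run_pipeline(
        [tables[k] for k in sorted(tables)], trained_model, PipelineConfig(seed=7)
    )
    return {"result": result, "truth": truth, "tables": tables}
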