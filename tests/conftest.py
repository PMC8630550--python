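import numpy as np
import pandas as pd
import pytest

from dualluc import SimulationSpec, TidyExperiment, default_spec, generate_experiment


@pytest.fixture
def two_condition_spec():
    """Tiny noiseless design: control vs geneA at a true fold change of 2."""
    return SimulationSpec(
        factors={"condition": ["control", "geneA"]},
        true_fold_change={"geneA": 2.0},
        replicates=3,
        transfection_sigma=0.0,
        measurement_sigma=0.0,
        seed=0,
    )


@pytest.fixture
def noiseless_experiment(two_condition_spec):
    exp, truth = generate_experiment(two_condition_spec)
    return exp, truth


@pytest.fixture
def full_plate_experiment():
    """72-well 3x4x2 experiment with realistic noise (seed 11)."""
    exp, truth = generate_experiment(default_spec(seed=11))
    return exp, truth


@pytest.fixture
def manual_experiment():
    """Hand-built 6-well table with easily checked numbers."""
    data = pd.DataFrame(
        {
            "well": ["A01", "A02", "A03", "B01", "B02", "B03"],
            "condition": ["control"] * 3 + ["geneA"] * 3,
            "firefly": [1000.0, 1100.0, 900.0, 4000.0, 4400.0, 3600.0],
            "renilla": [500.0, 550.0, 450.0, 1000.0, 1100.0, 900.0],
        }
    )
    return TidyExperiment(data=data, factor_names=["condition"])
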