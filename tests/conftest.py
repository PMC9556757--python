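import numpy as np
import pandas as pd
import pytest

from coexmap.datamodel import (
    ExpressionMatrix,
    ExpressionStudy,
    TraitSchema,
    align_study,
)
from coexmap.simulate import PlantedModule, SimulationConfig, simulate_study


@pytest.fixture
def small_study() -> ExpressionStudy:
    """Hand-built 2x2 balanced study: 8 samples, 1 region, both sexes."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(8)]
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "animal_id": [f"a{i}" for i in range(8)],
            "sex": ["F", "F", "F", "F", "M", "M", "M", "M"],
            "region": ["NAc"] * 8,
            "treatment": ["VEH", "VEH", "THC", "THC"] * 2,
        }
    )
    traits = pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(8)],
            "D1": rng.normal(size=8),
            "D2": rng.normal(size=8),
            "novel_exploration": rng.normal(size=8),
            "social_preference": rng.normal(size=8),
        }
    )
    expr = ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=samples,
        )
    )
    return align_study(expr, design, traits, TraitSchema())


@pytest.fixture
def planted_study():
    """One-region, one-sex study with three clean planted modules."""
    config = SimulationConfig(
        seed=11,
        n_genes=200,
        n_animals_per_group=12,
        regions=("A",),
        sexes=("F",),
        noise_sd=0.3,
        modules=[
            PlantedModule(f"m{i}", "A", 50, ("F",), 0.9, 0.0) for i in range(3)
        ],
    )
    return simulate_study(config)
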