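import numpy as np
import pandas as pd
import pytest

from commflux.abundance import AbundanceTable
from commflux.models import MetabolicReconstruction, Reaction


@pytest.fixture
def chain_model() -> MetabolicReconstruction:
    """Uptake A (capacity 10) -> convert to B -> export B, maximize export."""
    return MetabolicReconstruction(
        taxon_id="chain",
        metabolites={"A": "extracellular", "B": "extracellular", "Ai": "internal"},
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10.0, 0.0, exchange=True),
            Reaction("uptake_A", {"A": -1.0, "Ai": 1.0}, 0.0, 1000.0),
            Reaction("convert", {"Ai": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0, exchange=True, objective=1.0),
        ],
    )


@pytest.fixture
def random_table() -> AbundanceTable:
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 500, size=(8, 12))
    counts[:, 0] += 1  # no all-zero rows
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(8)],
            columns=[f"g{j:02d}" for j in range(12)],
        )
    )


def make_metadata(sample_ids, groups, compartments=None, subjects=None, ages=None,
                  cohort="training"):
    n = len(sample_ids)
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else list(sample_ids),
            "group": groups,
            "compartment": compartments if compartments is not None else ["oral"] * n,
            "age": ages if ages is not None else rng.integers(20, 70, n).astype(float),
            "sex": ["F"] * n,
            "cohort": [cohort] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
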