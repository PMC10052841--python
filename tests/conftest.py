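import numpy as np
import pytest

from dipkit.io_formats import GenotypeMatrix, LocusDef
from dipkit.synthetic_data import (ContinentSpec, PopulationSpec,
                                   SyntheticConfig, make_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Two continents x two populations, 40 samples each, 20 loci."""
    cfg = SyntheticConfig(
        n_loci=20,
        continents=[
            ContinentSpec("Africa", 0.12, [
                PopulationSpec("AFR1", 40, 0.02),
                PopulationSpec("AFR2", 40, 0.02),
            ]),
            ContinentSpec("East_Asia", 0.10, [
                PopulationSpec("EAS1", 40, 0.01),
                PopulationSpec("EAS2", 40, 0.01),
            ]),
        ],
        seed=42,
    )
    return make_dataset(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-written 6-sample, 3-locus matrix with one missing call."""
    loci = [LocusDef("rsA"), LocusDef("rsB"), LocusDef("rsC")]
    dosage = np.array([
        [0, 1, 2],
        [1, 1, 2],
        [2, 0, 1],
        [1, 2, 0],
        [0, 2, np.nan],
        [2, 1, 1],
    ], dtype=float)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(6)],
        population=["P1", "P1", "P1", "P2", "P2", "P2"],
        continent=["C1", "C1", "C1", "C2", "C2", "C2"],
        loci=loci,
        dosage=dosage,
        sex=["M", "F", "M", "F", "M", "F"],
    )
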