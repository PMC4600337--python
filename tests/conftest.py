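"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

from hydromap.datatypes import CASE, CONTROL, OBLIGATE_CARRIER, GenotypeMatrix, MarkerRecord
from hydromap.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_population():
    """One default founder population (seed 0): (GenotypeMatrix, TruthRecord)."""
    return simulate_population(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def clean_population():
    """Error-free, fully observed population for forced-by-construction checks."""
    cfg = SimulationConfig(seed=1, genotyping_error_rate=0.0, missing_rate=0.0)
    return simulate_population(cfg)


def make_matrix(genotypes, phenotypes=None, chromosome="1", spacing=1000):
    """Hand-rolled GenotypeMatrix from a nested list of codes (samples x markers)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    sample_ids = [f"s{i}" for i in range(n)]
    if phenotypes is None:
        phenotypes = {s: CONTROL for s in sample_ids}
    else:
        phenotypes = {f"s{i}": p for i, p in enumerate(phenotypes)}
    markers = [
        MarkerRecord(f"m{j}", chromosome, spacing * (j + 1), ("A", "B"))
        for j in range(m)
    ]
    return GenotypeMatrix(sample_ids, phenotypes, markers, g)
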