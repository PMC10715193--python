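import numpy as np
import pandas as pd
import pytest

from cogscale import (
    AnnotationRecord,
    ScalingLaw,
    SimulationSpec,
    build_count_matrix,
    simulate_matrix,
)
from cogscale.simulate import PhylumSpec


@pytest.fixture
def taxon_map():
    return pd.DataFrame(
        {
            "domain": ["Bacteria", "Bacteria", "Archaea"],
            "phylum": ["Proteobacteria", "Firmicutes", "Euryarchaeota"],
        },
        index=pd.Index(["org1", "org2", "org3"], name="organism_id"),
    )


@pytest.fixture
def tiny_records():
    return [
        AnnotationRecord("org1", "p1", "KT"),
        AnnotationRecord("org1", "p2", "K"),
        AnnotationRecord("org2", "p1", "J"),
        AnnotationRecord("org2", "p2", "CCE"),
    ]


@pytest.fixture
def tiny_matrix(tiny_records, taxon_map):
    return build_count_matrix(tiny_records, taxon_map)


@pytest.fixture(scope="session")
def het_matrix():
    """Three categories with distinct exponents plus a linear filler."""
    laws = {
        "J": ScalingLaw(0.3, 1.0, 0.05),
        "E": ScalingLaw(1.0, -1.5, 0.05),
        "T": ScalingLaw(1.7, -4.0, 0.05),
    }
    spec = SimulationSpec(160, (100, 10000), laws, filler_category="S", seed=11)
    matrix, truth = simulate_matrix(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def phyla_matrix():
    """Two phyla whose exponents for category T differ by a known offset."""
    phyla = (
        PhylumSpec("Alpha", 0.5, {"T": -0.3}),
        PhylumSpec("Beta", 0.5, {"T": 0.3}),
    )
    spec = SimulationSpec(
        600,
        (300, 30000),
        {"T": ScalingLaw(1.0, -1.5, 0.08), "J": ScalingLaw(0.5, 0.0, 0.08)},
        phyla=phyla,
        filler_category="S",
        seed=23,
    )
    matrix, truth = simulate_matrix(spec)
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
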