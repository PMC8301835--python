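import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import couplonscan as cs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_ann() -> cs.GenomeAnnotation:
    """20 genes at fixed positions on a 1 kb circular chromosome."""
    rng = np.random.default_rng(0)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:02d}" for i in range(20)],
            "tss": np.sort(rng.choice(1000, size=20, replace=False)),
            "strand": rng.choice(["+", "-"], size=20),
        }
    )
    return cs.GenomeAnnotation(chromosome_length=1000, genes=genes)


@pytest.fixture(scope="session")
def small_spec() -> cs.SimulationSpec:
    """A scaled-down simulation: 400 genes on 400 kb, three regulators."""
    return cs.SimulationSpec(
        seed=42,
        n_genes=400,
        chromosome_length=400_000,
        cluster_halfwidth=20_000,
        regulators=(
            cs.RegulatorSpec("SigA", "sigma", 80, program="early"),
            cs.RegulatorSpec("SigB", "sigma", 60, program="late",
                             spatial_center=200_000, spatial_concentration=0.4),
            cs.RegulatorSpec("NapA", "NAP", 50, program="early",
                             spatial_center=50_000, spatial_concentration=0.6,
                             overlaps={"SigA": 0.4, "SigB": 0.2}),
        ),
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """(annotation, sequence, regulon set, time-course) for the small spec."""
    return cs.generate_dataset(small_spec)
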