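import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from metabarcode import pipeline
from metabarcode.synthetic_data import FamilySpec, simulate_genome_family


@pytest.fixture(scope="session")
def small_family():
    """A 4-genome family with known orthology truth (small, fast)."""
    spec = FamilySpec(
        n_genomes=4,
        n_core_families=10,
        n_accessory_families=5,
        gene_length_mean=450,
        gene_length_sd=60,
        protein_identity=0.8,
        seed=7,
    )
    return simulate_genome_family(spec)


@pytest.fixture(scope="session")
def small_pipeline(small_family):
    genomes, _truth = small_family
    return pipeline.build_barcodes(genomes, 3000)
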