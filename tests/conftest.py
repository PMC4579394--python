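import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panelimpute import HaplotypePanel, SimConfig, SiteRecord, make_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(alleles, positions=None, chrom="1"):
    """Small panel helper: haplotype-major 0/1 matrix -> HaplotypePanel."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_haps, n_sites = alleles.shape
    if positions is None:
        positions = [10 * (j + 1) for j in range(n_sites)]
    legend = [
        SiteRecord(chrom=chrom, pos=int(p), id=f"s{j}", ref="A", alt="C")
        for j, p in enumerate(positions)
    ]
    ids = [f"S{i // 2}_{i % 2 + 1}" for i in range(n_haps)]
    return HaplotypePanel(legend=legend, haplotype_ids=ids, alleles=alleles)


@pytest.fixture
def small_panel():
    """6 haplotypes x 10 sites, seeded, guaranteed polymorphic columns."""
    rng = np.random.default_rng(7)
    alleles = rng.integers(0, 2, size=(6, 10), dtype=np.uint8)
    alleles[0] = 1 - alleles[1]  # every column polymorphic
    return make_panel(alleles)


@pytest.fixture(scope="session")
def toy_config():
    return SimConfig(
        n_founders=15,
        n_sites=300,
        region_bp=600_000,
        n_ref_a=40,
        n_ref_b=30,
        n_study=20,
        typed_fraction=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_scenario(toy_config):
    return make_scenario(toy_config)


@pytest.fixture(scope="session")
def standard_scenario():
    """The package's standard evaluation condition (default SimConfig)."""
    return make_scenario(SimConfig(seed=0))
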