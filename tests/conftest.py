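import pytest

from loopweaver.synthetic_data import (
    CategoryMix,
    DegSpec,
    LandscapeSpec,
    generate_landscape,
)


@pytest.fixture(scope="session")
def default_landscape():
    """The default synthetic landscape (shared read-only across tests)."""
    return generate_landscape(LandscapeSpec(seed=7))


@pytest.fixture(scope="session")
def small_spec():
    """A compact landscape spec for fast closure checks."""
    return LandscapeSpec(
        n_chromosomes=1,
        chrom_length=6_000_000,
        n_genes=30,
        n_loops=6,
        loop_extent_range=(150_000, 400_000),
        n_peaks=30,
        category_mix=CategoryMix(direct=4, anchor_anchor=4, anchor_span=4,
                                 span_anchor=4),
        deg_spec=DegSpec(n_up=5, n_down=3),
        seed=11,
    )
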