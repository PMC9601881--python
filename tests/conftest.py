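import pytest
from hypothesis import settings

from mutscan import datasets
from mutscan.library_spec import (
    DegenerateCodonPattern,
    MutagenesisDesign,
    PoolRegion,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> MutagenesisDesign:
    """12-codon NNS design with two overlapping pools, offset 100."""
    return MutagenesisDesign(
        reference_cds=datasets.synthetic_reference_cds(12, seed=5),
        pattern=DegenerateCodonPattern.from_string("NNS"),
        pools=(PoolRegion("p1", 2, 8), PoolRegion("p2", 6, 12)),
        numbering_offset=100,
    )


@pytest.fixture(scope="session")
def single_pool_design() -> MutagenesisDesign:
    """8-codon NNS design with one pool, identity numbering."""
    return MutagenesisDesign(
        reference_cds=datasets.synthetic_reference_cds(8, seed=9),
        pattern=DegenerateCodonPattern.from_string("NNS"),
        pools=(PoolRegion("p1", 2, 7),),
        numbering_offset=0,
    )
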