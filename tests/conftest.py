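import numpy as np
import pytest

from famevol.synthetic_data import (
    GenomeLayoutSpec,
    SegmentalSpec,
    TandemSpec,
    simulate_genome_layout,
)


@pytest.fixture(scope="session")
def planted_genome():
    """Small genome with one 3-gene tandem array and one 5-anchor
    segmental block at target Ks 0.17, events far enough apart that
    the detection rules see them as separate."""
    spec = GenomeLayoutSpec(
        n_chromosomes=2, genes_per_chromosome=40,
        planted_tandem=[TandemSpec(chromosome=0, start_index=2, size=3,
                                   intervening=1)],
        planted_segmental=[SegmentalSpec(source_chromosome=0,
                                         source_start=25,
                                         target_chromosome=1,
                                         target_start=10,
                                         n_anchors=5, target_ks=0.17)])
    return simulate_genome_layout(spec, seed=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
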