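import numpy as np
import pytest

from mitolineage import PileupMatrix, SimConfig, SimVariant
from mitolineage.pileup import ALLELE_INDEX


def make_pileup(sites, genome_length=16569, sample_id="test"):
    """Build a PileupMatrix from {position: (ref, {allele: (fwd, rev)})}."""
    positions = sorted(sites)
    refs, counts = [], []
    for pos in positions:
        ref, alleles = sites[pos]
        c = np.zeros((4, 2), dtype=np.int64)
        for allele, (fwd, rev) in alleles.items():
            c[ALLELE_INDEX[allele]] = (fwd, rev)
        refs.append(ref)
        counts.append(c)
    return PileupMatrix(
        sample_id,
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype="U1"),
        np.stack(counts) if counts else np.zeros((0, 4, 2), dtype=np.int64),
        genome_length,
    )


@pytest.fixture
def simple_site():
    """Depth-100 G site at 3010 with a balanced 22-read A alternate."""
    return make_pileup({3010: ("G", {"G": (40, 38), "A": (12, 10)})})


@pytest.fixture
def two_clone_config():
    """Fixed-seed 2-clone population (4 + 2 variants), depth 100, VAF >= 0.1."""
    return SimConfig(
        n_cells=150,
        clone_fractions=[0.5, 0.5],
        clone_variants=[
            [SimVariant(1000, "A", "G", 0.30), SimVariant(2000, "C", "T", 0.20),
             SimVariant(4000, "G", "A", 0.15), SimVariant(5000, "T", "A", 0.10)],
            [SimVariant(8000, "A", "C", 0.25), SimVariant(9000, "C", "G", 0.12)],
        ],
        depth_model="constant",
        depth_mean=100,
        error_rate=1e-3,
        seed=7,
    )
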