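import numpy as np
import pytest

from dockpot.pair_stats import DistanceBinning, PairCountTable
from dockpot.structure_io import PartnerStructure, PseudoResidue

BACKBONE_OFFSETS = {
    "N": np.array([-1.5, 0.5, 0.0]),
    "CA": np.array([0.5, -0.5, 0.0]),
    "C": np.array([1.5, 0.5, 0.0]),
    "O": np.array([-0.5, -0.5, 0.0]),
}


def make_partner(label, chain, residues, backbone=True):
    """Build a partner from (aa, ss3, centroid) triples."""
    out = []
    for k, (aa, ss, c) in enumerate(residues):
        c = np.asarray(c, dtype=float)
        bb = {n: c + off for n, off in BACKBONE_OFFSETS.items()} if backbone else {}
        out.append(PseudoResidue(chain, k + 1, aa, ss, c, backbone=bb))
    return PartnerStructure(label=label, residues=out)


def random_count_table(rng, binning=None, scale=50, min_count=0):
    """Symmetric random PairCountTable with consistent marginals."""
    binning = binning or DistanceBinning()
    t = PairCountTable(binning=binning)
    c = rng.integers(min_count, min_count + scale, size=t.counts.shape)
    c = c + c.transpose(1, 0, 2)
    t.counts = c.astype(np.int64)
    t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
    t.n_residue = rng.integers(1, 100, size=60).astype(np.int64)
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
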