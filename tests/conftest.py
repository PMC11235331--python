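import numpy as np
import pytest
import scipy.sparse as sp

from txdemux.matrix import AlleleCountMatrix, SNVSite
from txdemux.simulate import GenotypePair, SimConfig, simulate_sample


def make_matrix(alt, total, chroms=None):
    """Build an AlleleCountMatrix from dense arrays (sites x cells)."""
    alt = np.asarray(alt)
    total = np.asarray(total)
    n_sites = alt.shape[0]
    chroms = chroms or ["1"] * n_sites
    sites = [
        SNVSite(chrom=chroms[i], pos=100 + i, ref_allele="A", alt_allele="G", id=i)
        for i in range(n_sites)
    ]
    barcodes = [f"BC{j:04d}" for j in range(alt.shape[1])]
    return AlleleCountMatrix(
        sites=sites, barcodes=barcodes, alt=sp.csr_matrix(alt), total=sp.csr_matrix(total)
    )


def opposite_pair(n_sites, error=0.005):
    """Two genotypes homozygous-opposite at every site; uniform coverage."""
    return GenotypePair(
        pop_af=np.full(n_sites, 0.5),
        gt1=np.zeros(n_sites, dtype=int),
        gt2=np.full(n_sites, 2, dtype=int),
        true_af1=np.full(n_sites, error),
        true_af2=np.full(n_sites, 1.0 - error),
        fp_mask=np.zeros(n_sites, dtype=bool),
        site_weights=np.full(n_sites, 1.0 / n_sites),
    )


@pytest.fixture(scope="session")
def sim_pair():
    from txdemux.simulate import draw_genotypes

    return draw_genotypes(400, seed=7, config=SimConfig(n_sites=400, seed=7))


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(n_total=400, n_sites=400, minor_counts=(100,), seed=7)


@pytest.fixture(scope="session")
def mixed_sample(sim_pair, sim_cfg):
    """A 300 GT1 + 100 GT2 + 10 doublet sample, 10% ambient."""
    return simulate_sample(sim_pair, 100, 0.1, sim_cfg, seed=42)


@pytest.fixture(scope="session")
def mixed_result(mixed_sample):
    from txdemux.demux import DemuxConfig, demultiplex

    return demultiplex(mixed_sample.matrix, DemuxConfig(seed=1))
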