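import numpy as np
import pytest

from poolscan import poolstats, sim


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale profile of the full neutral design (λ=10, 2 Mb chromosomes)."""
    return sim.SimConfig.desk_scale()


@pytest.fixture(scope="session")
def small_genome(desk_config):
    """A 6-chromosome pseudo-genome at desk scale, shared across tests.

    Returns (dataset, truth, snps): pooled reads, true frequencies (both
    restricted to MAF-passing sites) and the filtered SNP table.
    """
    import dataclasses

    config = dataclasses.replace(desk_config, n_chrom=6)
    dataset, truth = sim.simulate_pseudo_genome(config, seed=424242)
    snps = poolstats.filter_snps(dataset)
    return config, dataset, truth, snps


def make_snp_table(freqs, depths=None, chrom=None, pos=None, pools=None):
    """SNPTable straight from frequency/depth arrays (bypasses read sampling)."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if depths is None:
        depths = np.full_like(freqs, 20.0)
    else:
        depths = np.broadcast_to(np.asarray(depths, dtype=float), freqs.shape).copy()
    n = freqs.shape[0]
    return poolstats.SNPTable(
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * n, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n + 1) * 100),
        major=np.asarray(["A"] * n, dtype=object),
        minor=np.asarray(["T"] * n, dtype=object),
        counts=freqs * depths,
        depths=depths,
        pools=pools or [f"pool{i}" for i in range(freqs.shape[1])],
    )
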