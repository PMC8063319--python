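"""Coalescent backend for the neutral three-deme history (msprime DTWF).

The forward model is strictly neutral, so its site-frequency output is
matched in distribution by a backward-in-time simulation with the same
demography. Two details make this a faithful drop-in for the forward engine:

* whole demes are sampled (n = 2N chromosomes per deme), so the discrete-time
  Wright-Fisher model (``dtwf``) is used rather than the Hudson coalescent,
  which assumes n << N;
* the forward run starts from a monomorphic ancestral deme, which is emulated
  by collapsing the ancestral deme to a single diploid at the founding time
  (t_split + t_burn), forcing all lineages to coalesce there and leaving no
  variation older than the burn-in.

Mutations use a binary infinite-sites model on a continuous genome.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_coalescent"]


def simulate_coalescent(n_anc: int, t_burn: int, n_demes: int, n_deme: int,
                        t_split: int, chrom_len: int, mu: float, rec: float,
                        seed) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one chromosome; return (positions, per-deme frequencies).

    Same contract as :func:`poolscan._forward.simulate_forward`.
    """
    import msprime  # deferred: keeps import cost out of CLI startup

    rng = np.random.default_rng(seed)
    # msprime wants seeds in [1, 2^32); stay below 2^31 for portability
    s_anc = int(rng.integers(1, 2**31 - 1))
    s_mut = int(rng.integers(1, 2**31 - 1))

    dem = msprime.Demography()
    dem.add_population(name="anc", initial_size=n_anc)
    names = [f"d{i}" for i in range(n_demes)]
    for name in names:
        dem.add_population(name=name, initial_size=n_deme)
    if t_split > 0:
        dem.add_population_split(time=t_split, derived=names, ancestral="anc")
        dem.add_population_parameters_change(
            time=t_split + t_burn, population="anc", initial_size=1)
        dem.sort_events()
        samples = {name: n_deme for name in names}
    else:
        # degenerate split: the demes are three samples of the ancestral deme
        dem.add_population_parameters_change(
            time=t_burn, population="anc", initial_size=1)
        samples = {"anc": n_demes * n_deme}

    ts = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=chrom_len,
        recombination_rate=rec, model="dtwf", ploidy=2, random_seed=s_anc)
    ts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=s_mut)

    if ts.num_sites == 0:
        return np.empty(0, dtype=np.int64), np.zeros((0, n_demes))

    geno = ts.genotype_matrix()  # (sites, 2 * n_demes * n_deme), 0/1
    two_n = 2 * n_deme
    freqs = np.stack(
        [geno[:, i * two_n:(i + 1) * two_n].mean(axis=1) for i in range(n_demes)],
        axis=1)
    seg = ~(np.all(freqs == 0.0, axis=1) | np.all(freqs == 1.0, axis=1))
    pos = np.floor(ts.sites_position[seg]).astype(np.int64) + 1
    freqs = freqs[seg]
    uniq, first = np.unique(pos, return_index=True)
    return uniq, freqs[first]
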