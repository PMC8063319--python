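"""Individual-based forward Wright-Fisher engine.

Reference implementation of the neutral three-deme history: discrete
non-overlapping generations, random mating with selfing allowed, Poisson
crossovers and Poisson mutations per gamete, infinite-sites mutation on a
continuous chromosome (a draw colliding with an occupied position is
redrawn; no back mutation).

This engine is exact but slow; the msprime backend in
:mod:`poolscan._coalescent` is the desk-scale default and is held to agree
with this one (see the engine-equivalence tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_forward"]


class _Deme:
    """One panmictic deme: 2N haplotypes over the currently segregating sites."""

    def __init__(self, n_dip: int, positions: np.ndarray, haplotypes: np.ndarray):
        self.n_dip = n_dip
        self.positions = positions  # float positions in (0, L], sorted
        self.H = haplotypes  # (2N, S) bool
        self.fixed: set = set()  # positions fixed since this deme's founding

    @classmethod
    def monomorphic(cls, n_dip: int) -> "_Deme":
        return cls(n_dip, np.empty(0), np.zeros((2 * n_dip, 0), dtype=bool))

    def freq(self, pos_index: dict) -> np.ndarray:
        """Derived-allele frequency at each position of ``pos_index``."""
        out = np.zeros(len(pos_index))
        counts = self.H.mean(axis=0)
        for p, f in zip(self.positions, counts):
            out[pos_index[p]] = f
        for p in self.fixed:
            if p in pos_index:
                out[pos_index[p]] = 1.0
        return out


def _gametes(deme: _Deme, n_children: int, rec: float, length: float,
             rng: np.random.Generator) -> np.ndarray:
    """Draw 2*n_children recombinant gametes from ``deme``."""
    H, positions = deme.H, deme.positions
    n_gam = 2 * n_children
    parents = rng.integers(0, deme.n_dip, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    n_cx = rng.poisson(rec * length, size=n_gam)
    out = np.empty((n_gam, H.shape[1]), dtype=bool)
    for g in range(n_gam):
        a = H[2 * parents[g] + start[g]]
        if n_cx[g] == 0 or H.shape[1] == 0:
            out[g] = a
        else:
            b = H[2 * parents[g] + 1 - start[g]]
            breaks = np.sort(rng.uniform(0.0, length, n_cx[g]))
            odd = (np.searchsorted(breaks, positions) % 2) == 1
            out[g] = np.where(odd, b, a)
    return out


def _mutate(positions: np.ndarray, H: np.ndarray, mu: float, length: float,
            occupied: set, rng: np.random.Generator):
    """Add Poisson(2N*mu*L) new infinite-sites mutations, one gamete each."""
    n_gam = H.shape[0]
    n_mut = rng.poisson(n_gam * mu * length)
    if n_mut == 0:
        return positions, H
    new_pos = []
    for _ in range(n_mut):
        p = rng.uniform(0.0, length)
        while p in occupied or p == 0.0:
            p = rng.uniform(0.0, length)
        occupied.add(p)
        new_pos.append(p)
    carriers = rng.integers(0, n_gam, size=n_mut)
    new_cols = np.zeros((n_gam, n_mut), dtype=bool)
    new_cols[carriers, np.arange(n_mut)] = True
    positions = np.concatenate([positions, new_pos])
    H = np.concatenate([H, new_cols], axis=1)
    order = np.argsort(positions)
    return positions[order], H[:, order]


def _prune(deme: _Deme, record_fixed: bool) -> None:
    counts = deme.H.sum(axis=0)
    lost = counts == 0
    fixed = counts == deme.H.shape[0]
    if record_fixed:
        deme.fixed.update(deme.positions[fixed])
    keep = ~(lost | fixed)
    if not keep.all():
        deme.positions = deme.positions[keep]
        deme.H = deme.H[:, keep]


def _step(deme: _Deme, mu: float, rec: float, length: float, occupied: set,
          rng: np.random.Generator, record_fixed: bool) -> None:
    H = _gametes(deme, deme.n_dip, rec, length, rng)
    deme.positions, deme.H = _mutate(deme.positions, H, mu, length, occupied, rng)
    _prune(deme, record_fixed)


def simulate_forward(n_anc: int, t_burn: int, n_demes: int, n_deme: int,
                     t_split: int, chrom_len: int, mu: float, rec: float,
                     seed) -> tuple[np.ndarray, np.ndarray]:
    """Run the forward model and return (positions, per-deme frequencies).

    Positions are 1-based integer bp, strictly increasing; frequencies have
    shape (n_sites, n_demes). Only sites segregating or divergent across the
    deme set are returned (globally fixed and globally lost sites dropped).
    """
    rng = np.random.default_rng(seed)
    occupied: set = set()
    anc = _Deme.monomorphic(n_anc)
    for _ in range(t_burn):
        _step(anc, mu, rec, float(chrom_len), occupied, rng, record_fixed=False)

    # Founding: each deme is one WF generation drawn from the ancestral pool.
    demes = []
    for _ in range(n_demes):
        H = _gametes(anc, n_deme, rec, float(chrom_len), rng)
        d = _Deme(n_deme, anc.positions.copy(), H)
        d.positions, d.H = _mutate(d.positions, d.H, mu, float(chrom_len), occupied, rng)
        _prune(d, record_fixed=True)
        demes.append(d)
    for _ in range(t_split):
        for d in demes:
            _step(d, mu, rec, float(chrom_len), occupied, rng, record_fixed=True)

    all_pos = sorted(set().union(*[set(d.positions) for d in demes],
                                 *[d.fixed for d in demes]))
    pos_index = {p: i for i, p in enumerate(all_pos)}
    freqs = np.stack([d.freq(pos_index) for d in demes], axis=1) \
        if all_pos else np.zeros((0, n_demes))
    # drop globally fixed (divergence requires at least one deme different)
    seg = ~(np.all(freqs == 0.0, axis=1) | np.all(freqs == 1.0, axis=1))
    pos = np.asarray(all_pos)[seg]
    freqs = freqs[seg]
    # continuous -> 1-based integer bp; collisions after flooring are dropped
    ipos = np.floor(pos).astype(np.int64) + 1
    uniq, first = np.unique(ipos, return_index=True)
    return uniq, freqs[first]
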