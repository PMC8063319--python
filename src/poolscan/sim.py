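"""Neutral three-population Wright-Fisher simulator with pool-seq sampling.

The model: a single ancestral deme of ``n_anc`` diploids evolves for
``t_burn`` generations from a monomorphic start, then splits into
``n_demes`` isolated demes of ``n_deme`` diploids each, which drift
independently (no migration) for ``t_split`` generations under neutral
infinite-sites mutation (rate ``mu`` per bp per generation) and uniform
crossover (``rec`` per bp per generation). ``n_chrom`` independent
chromosomes of ``chrom_len`` bp form one "pseudo-genome".

Pool sequencing is emulated per site and per deme: an integer depth is drawn
from a rounded, rejection-truncated normal (``depth_mean``, ``depth_sd``,
bounds [``depth_min``, ``depth_max``]), and the derived-read count is
binomial in the deme's true allele frequency. A global minor-allele-frequency
filter (pooled read counts across demes) is applied before output.

A scaling knob ``scale`` = λ rescales N → N/λ, t → t/λ, μ → λμ, r → λr,
preserving the population-scaled parameters 4Nμ, 4Nr and t/2N so that
desk-scale runs are statistically comparable to the full design.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from ._coalescent import simulate_coalescent
from ._forward import simulate_forward
from .syncio import SyncRecord, write_sync

__all__ = [
    "SimConfig", "TruthPanel", "PoolDataset",
    "scale_config", "simulate_history", "sample_pool",
    "simulate_pseudo_genome", "write_sync", "load_config",
]

#: Simulated derived alleles are written as T on an A reference.
REF_BASE = "A"
ALT_BASE = "T"
_REF_COL = 0  # index of A in A:T:C:G:N:del
_ALT_COL = 1  # index of T

ENGINES = ("msprime", "forward")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the neutral simulation study.

    Defaults are the full-scale design: ancestral deme of 1000 diploids,
    1000-generation burn-in, split into three isolated demes of 1000 for
    2500 generations; 75 Mb chromosomes, mu = 2e-7 and rec = 1.5e-8 per bp
    per generation, 30 chromosomes per pseudo-genome; pool depths from a
    truncated normal with mean 23, sd 5 on [15, 50]; global MAF > 0.05.
    """

    n_anc: int = 1000
    t_burn: int = 1000
    n_demes: int = 3
    n_deme: int = 1000
    t_split: int = 2500
    chrom_len: int = 75_000_000
    mu: float = 2e-7
    rec: float = 1.5e-8
    n_chrom: int = 30
    depth_mean: float = 23.0
    depth_sd: float = 5.0
    depth_min: int = 15
    depth_max: int = 50
    maf_min: float = 0.05
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_anc", "n_demes", "n_deme", "chrom_len", "n_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("t_burn", "t_split"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mu", "rec", "depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.depth_min <= self.depth_mean <= self.depth_max):
            raise ValueError("need depth_min <= depth_mean <= depth_max")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def desk_scale(cls, **overrides) -> "SimConfig":
        """The λ=10, 2 Mb desk profile of the full design."""
        base = cls(**{**dict(chrom_len=2_000_000), **overrides})
        return scale_config(base, 10.0)


def load_config(path: Union[str, Path]) -> SimConfig:
    """Load a SimConfig from a YAML or JSON file (exactly the config fields)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of SimConfig fields")
    return SimConfig.from_dict(data)


def scale_config(config: SimConfig, lam: float) -> SimConfig:
    """Rescale a configuration by λ ≥ 1, preserving 4Nμ, 4Nr and t/2N.

    N → N/λ (rounded), t → t/λ (rounded), μ → λμ, r → λr. Depth model,
    ``maf_min`` and ``chrom_len`` are unchanged. Rejects a λ that drives any
    deme below 20 diploids, where drift is no longer comparable.
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    n_anc = round(config.n_anc / lam)
    n_deme = round(config.n_deme / lam)
    if min(n_anc, n_deme) < 20:
        raise ValueError(
            f"scale {lam} would reduce a deme to {min(n_anc, n_deme)} < 20 diploids")
    return dataclasses.replace(
        config,
        n_anc=n_anc, n_deme=n_deme,
        t_burn=round(config.t_burn / lam), t_split=round(config.t_split / lam),
        mu=config.mu * lam, rec=config.rec * lam,
        scale=config.scale * lam,
    )


@dataclass
class TruthPanel:
    """Ground truth for simulated sites: true per-deme allele frequencies."""

    chrom: np.ndarray      # per-site chromosome label
    positions: np.ndarray  # 1-based bp, strictly increasing within chrom
    freqs: np.ndarray      # (n_sites, n_demes) derived-allele frequency

    def __post_init__(self):
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def true_fst_windows(self, window: int = 100_000, n_haplotypes: Optional[int] = None
                         ) -> "pandas.DataFrame":  # noqa: F821
        """Multi-deme Weir-Cockerham FST per window from the true frequencies.

        ``n_haplotypes`` is the haploid deme size used as the sample size
        (2 * n_deme of the generating config; defaults to a large value so the
        finite-sample correction is negligible).
        """
        import pandas as pd

        from .poolstats import fst_snp

        n = float(n_haplotypes if n_haplotypes is not None else 10_000)
        depths = np.full_like(self.freqs, n)
        num, den, _ = fst_snp(depths, self.freqs, method="wc")
        win = (self.positions - 1) // window
        rows = []
        for chrom in pd.unique(self.chrom):
            m = self.chrom == chrom
            for w in np.unique(win[m]):
                sel = m & (win == w)
                d = den[sel].sum()
                rows.append({
                    "chrom": chrom,
                    "start": int(w * window + 1), "end": int((w + 1) * window),
                    "n_sites": int(sel.sum()),
                    "true_fst": num[sel].sum() / d if d > 0 else np.nan,
                })
        return pd.DataFrame(rows)

    def write(self, path: Union[str, Path]) -> None:
        import pandas as pd

        df = pd.DataFrame({"chrom": self.chrom, "pos": self.positions})
        for i in range(self.freqs.shape[1]):
            df[f"freq_d{i}"] = self.freqs[:, i]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PoolDataset:
    """Array-backed pooled read counts at simulated SNPs (sync semantics)."""

    chrom: np.ndarray       # per-site chromosome label
    pos: np.ndarray         # 1-based bp
    alt_counts: np.ndarray  # (n_sites, n_pools) derived-allele read counts
    depths: np.ndarray      # (n_sites, n_pools) total read depths
    pools: Sequence[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def global_maf(self) -> np.ndarray:
        """Minor-allele frequency from read counts pooled across all pools."""
        tot = self.depths.sum(axis=1)
        f = self.alt_counts.sum(axis=1) / np.maximum(tot, 1)
        return np.minimum(f, 1.0 - f)

    def to_records(self) -> Iterator[SyncRecord]:
        for i in range(self.n_sites):
            counts = []
            for j in range(self.n_pools):
                pool = [0, 0, 0, 0, 0, 0]
                alt = int(self.alt_counts[i, j])
                pool[_REF_COL] = int(self.depths[i, j]) - alt
                pool[_ALT_COL] = alt
                counts.append(tuple(pool))
            yield SyncRecord(chrom=str(self.chrom[i]), pos=int(self.pos[i]),
                             ref=REF_BASE, counts=tuple(counts))

    def write_sync(self, path) -> None:
        write_sync(self.to_records(), path)

    @classmethod
    def concat(cls, parts: Sequence["PoolDataset"]) -> "PoolDataset":
        return cls(
            chrom=np.concatenate([p.chrom for p in parts]),
            pos=np.concatenate([p.pos for p in parts]),
            alt_counts=np.concatenate([p.alt_counts for p in parts]),
            depths=np.concatenate([p.depths for p in parts]),
            pools=parts[0].pools,
        )


def simulate_history(config: SimConfig, chrom_seed: int, engine: str = "msprime",
                     chrom_name: str = "chr1") -> TruthPanel:
    """Simulate one chromosome; return true per-deme allele frequencies.

    ``engine`` selects the individual-based forward implementation
    (``"forward"``) or the equivalent msprime DTWF backend (``"msprime"``,
    default — orders of magnitude faster at desk scale).
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    fn = simulate_coalescent if engine == "msprime" else simulate_forward
    pos, freqs = fn(config.n_anc, config.t_burn, config.n_demes, config.n_deme,
                    config.t_split, config.chrom_len, config.mu, config.rec,
                    chrom_seed)
    return TruthPanel(chrom=np.full(len(pos), chrom_name, dtype=object),
                      positions=pos, freqs=freqs)


def _truncated_normal_depths(shape, mean, sd, lo, hi, rng) -> np.ndarray:
    """Rounded rejection-sampled truncated normal; bounds applied after rounding."""
    d = np.rint(rng.normal(mean, sd, size=shape))
    bad = (d < lo) | (d > hi)
    while bad.any():
        d[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum())))
        bad = (d < lo) | (d > hi)
    return d.astype(np.int64)


def sample_pool(truth: TruthPanel, config: SimConfig, seed) -> PoolDataset:
    """Pool-sequence the true frequencies: per-site, per-deme truncated-normal
    depths and binomial derived-read counts."""
    rng = np.random.default_rng(seed)
    n_pools = truth.freqs.shape[1]
    depths = _truncated_normal_depths(
        (truth.n_sites, n_pools), config.depth_mean, config.depth_sd,
        config.depth_min, config.depth_max, rng)
    alt = rng.binomial(depths, truth.freqs)
    return PoolDataset(chrom=truth.chrom.copy(), pos=truth.positions.copy(),
                       alt_counts=alt, depths=depths,
                       pools=[f"pool{i}" for i in range(n_pools)])


def simulate_pseudo_genome(config: SimConfig, seed: int, engine: str = "msprime"
                           ) -> tuple[PoolDataset, TruthPanel]:
    """Simulate ``config.n_chrom`` independent chromosomes, pool-sample them,
    and apply the global MAF filter.

    All randomness flows deterministically from (``seed``, chromosome index):
    the same inputs give byte-identical sync output. The truth panel is
    returned restricted to the sites that pass the MAF filter.
    """
    panels, pools = [], []
    for k in range(config.n_chrom):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))
        hist_seed, pool_seed = ss.generate_state(2) % (2**31 - 1)
        name = f"chr{k + 1}"
        panel = simulate_history(config, int(hist_seed), engine=engine,
                                 chrom_name=name)
        ds = sample_pool(panel, config, int(pool_seed))
        keep = ds.global_maf() > config.maf_min
        panels.append(TruthPanel(chrom=panel.chrom[keep],
                                 positions=panel.positions[keep],
                                 freqs=panel.freqs[keep]))
        pools.append(PoolDataset(chrom=ds.chrom[keep], pos=ds.pos[keep],
                                 alt_counts=ds.alt_counts[keep],
                                 depths=ds.depths[keep], pools=ds.pools))
    dataset = PoolDataset.concat(pools)
    truth = TruthPanel(
        chrom=np.concatenate([p.chrom for p in panels]),
        positions=np.concatenate([p.positions for p in panels]),
        freqs=np.concatenate([p.freqs for p in panels]))
    return dataset, truth
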