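"""Pool-seq SNP filtering and window divergence statistics.

Per-site allele frequencies are read-count frequencies: at each retained SNP
the read depth n_i of pool i is used as the haploid sample size, which is
standard pool-seq practice (the finite number of pooled chromosomes is
ignored). Two per-SNP FST estimators are provided:

* ``wc`` — the Weir & Cockerham (1984) estimator in its two-level haploid
  (allele-count) form: variance components a (among populations) and b
  (within), theta = a / (a + b). Pooled reads carry no genotype pairing, so
  there is no within-individual component.
* ``karlsson`` — the two-population estimator of Karlsson et al. (2007) as
  popularised by PoPoolation2's ``--karlsson`` option: N = (p1-p2)^2
  - h1/n1 - h2/n2, D = N + h1 + h2 with h_i the unbiased heterozygosity.

Window statistics aggregate per-SNP components as a ratio of sums over
non-overlapping windows (default 100 kb). Nucleotide diversity uses the
depth-corrected per-site heterozygosity pi = n/(n-1) * 2p(1-p); absolute
divergence dxy = p1(1-p2) + p2(1-p1). Window pi/dxy are sums over variant
sites divided by the number of covered sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .syncio import BASES, SyncRecord, read_sync

__all__ = [
    "FilterParams", "SNPTable",
    "read_sync", "read_sync_dataset", "filter_snps",
    "fst_snp", "fst_windows", "diversity_windows", "window_stats",
    "bin_summary", "genome_summary",
]

DEFAULT_WINDOW = 100_000
DEFAULT_MIN_SNPS = 10
DEFAULT_BIN_THRESHOLDS = (0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class FilterParams:
    """SNP retention rules.

    A site is kept when it (1) is biallelic (exactly two bases with nonzero
    pooled counts; N and deletion columns are never counted as alleles),
    (2) has global minor-allele frequency (from counts summed across pools)
    above ``maf_min``, (3) carries at least ``min_minor_copies`` pooled
    copies of the minor allele, and (4) has every pool's depth within
    [``depth_min``, ``depth_max``]. Sites inside ``exclude`` intervals
    (chrom, start, end — 1-based inclusive) are dropped.
    """

    require_biallelic: bool = True
    maf_min: float = 0.05
    min_minor_copies: int = 2
    depth_min: int = 15
    depth_max: int = 50
    exclude: tuple = ()

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must be <= depth_max")


@dataclass
class SNPTable:
    """Filtered biallelic SNPs: per-pool minor-allele counts and depths.

    ``counts``/``depths`` have shape (n_snps, n_pools); ``freqs`` is the
    per-pool minor-allele read frequency c_i / n_i.
    """

    chrom: np.ndarray
    pos: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    counts: np.ndarray
    depths: np.ndarray
    pools: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.pools:
            self.pools = [f"pool{i}" for i in range(self.counts.shape[1])]

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.depths

    def pool_index(self, pool: Union[str, int]) -> int:
        return pool if isinstance(pool, int) else list(self.pools).index(pool)

    def to_records(self):
        """Re-emit the table as sync records (major/minor as A/T columns)."""
        from .syncio import SyncRecord

        base_col = {b: k for k, b in enumerate(BASES)}
        for i in range(self.n_snps):
            pools = []
            for j in range(self.n_pools):
                pool = [0, 0, 0, 0, 0, 0]
                pool[base_col[str(self.minor[i])]] = int(self.counts[i, j])
                pool[base_col[str(self.major[i])]] = int(
                    self.depths[i, j] - self.counts[i, j])
                pools.append(tuple(pool))
            yield SyncRecord(chrom=str(self.chrom[i]), pos=int(self.pos[i]),
                             ref=str(self.major[i]), counts=tuple(pools))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                           "major": self.major, "minor": self.minor})
        for j, name in enumerate(self.pools):
            df[f"count_{name}"] = self.counts[:, j]
            df[f"depth_{name}"] = self.depths[:, j]
            df[f"freq_{name}"] = self.freqs[:, j]
        return df


def read_sync_dataset(path: Union[str, Path], pools: Optional[Sequence[str]] = None):
    """Read a whole sync file into arrays: (chrom, pos, ref, counts).

    ``counts`` has shape (n_sites, n_pools, 6). Faster, non-streaming
    counterpart of :func:`read_sync` for pipeline use.
    """
    chroms, positions, refs, counts = [], [], [], []
    for rec in read_sync(path):
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        counts.append(rec.counts)
    n_pools = len(counts[0]) if counts else 0
    arr = np.asarray(counts, dtype=np.int64).reshape(len(counts), n_pools, 6) \
        if counts else np.zeros((0, 0, 6), dtype=np.int64)
    if pools is None:
        pools = [f"pool{i}" for i in range(n_pools)]
    return (np.asarray(chroms, dtype=object), np.asarray(positions, dtype=np.int64),
            np.asarray(refs, dtype=object), arr, list(pools))


def _in_excluded(chrom, pos, exclude) -> np.ndarray:
    out = np.zeros(len(pos), dtype=bool)
    for (c, start, end) in exclude:
        out |= (chrom == c) & (pos >= start) & (pos <= end)
    return out


def filter_snps(records: Union[Iterable[SyncRecord], tuple, "PoolDataset"],  # noqa: F821
                params: FilterParams = FilterParams(),
                pools: Optional[Sequence[str]] = None) -> SNPTable:
    """Apply the SNP retention rules and emit per-pool minor-allele data.

    Accepts an iterable of :class:`SyncRecord`, the array tuple returned by
    :func:`read_sync_dataset`, or a :class:`poolscan.sim.PoolDataset`.
    Filtering is idempotent: re-filtering a filtered table's sites changes
    nothing.
    """
    from .sim import PoolDataset  # local import to avoid a cycle

    if isinstance(records, PoolDataset):
        counts = np.zeros((records.n_sites, records.n_pools, 6), dtype=np.int64)
        counts[:, :, 0] = records.depths - records.alt_counts
        counts[:, :, 1] = records.alt_counts
        chrom, pos = records.chrom, records.pos
        pools = list(records.pools)
    elif isinstance(records, tuple):
        chrom, pos, _refs, counts, pools = records
    else:
        chrom, pos, _refs, counts, detected = read_sync_dataset_records(records)
        pools = pools or detected

    if counts.shape[0] == 0:
        return SNPTable(chrom=np.empty(0, dtype=object), pos=np.empty(0, np.int64),
                        major=np.empty(0, dtype=object), minor=np.empty(0, dtype=object),
                        counts=np.zeros((0, len(pools or []))),
                        depths=np.zeros((0, len(pools or []))), pools=pools or [])

    base_counts = counts[:, :, :4]                 # N/del never count as alleles
    pooled = base_counts.sum(axis=1)               # (sites, 4)
    n_alleles = (pooled > 0).sum(axis=1)
    keep = np.ones(len(pos), dtype=bool)
    if params.require_biallelic:
        keep &= n_alleles == 2
    else:
        keep &= n_alleles >= 2

    # major/minor from pooled counts over the two top alleles
    order = np.argsort(pooled, axis=1)             # ascending
    major_idx = order[:, -1]
    minor_idx = order[:, -2]
    rows = np.arange(len(pos))
    major_tot = pooled[rows, major_idx].astype(float)
    minor_tot = pooled[rows, minor_idx].astype(float)
    depth_tot = major_tot + minor_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(depth_tot > 0, minor_tot / depth_tot, 0.0)
    keep &= maf > params.maf_min
    keep &= minor_tot >= params.min_minor_copies

    # per-pool depth over the two segregating alleles
    per_pool_minor = np.take_along_axis(
        base_counts, minor_idx[:, None, None], axis=2)[:, :, 0]
    per_pool_major = np.take_along_axis(
        base_counts, major_idx[:, None, None], axis=2)[:, :, 0]
    per_pool_depth = per_pool_minor + per_pool_major
    keep &= np.all((per_pool_depth >= params.depth_min)
                   & (per_pool_depth <= params.depth_max), axis=1)

    if params.exclude:
        keep &= ~_in_excluded(np.asarray(chrom), np.asarray(pos), params.exclude)

    base_names = np.array(BASES[:4], dtype=object)
    return SNPTable(
        chrom=np.asarray(chrom, dtype=object)[keep],
        pos=np.asarray(pos)[keep],
        major=base_names[major_idx[keep]],
        minor=base_names[minor_idx[keep]],
        counts=per_pool_minor[keep].astype(float),
        depths=per_pool_depth[keep].astype(float),
        pools=list(pools),
    )


def read_sync_dataset_records(records: Iterable[SyncRecord]):
    chroms, positions, refs, counts = [], [], [], []
    for rec in records:
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        counts.append(rec.counts)
    n_pools = len(counts[0]) if counts else 0
    arr = (np.asarray(counts, dtype=np.int64).reshape(len(counts), n_pools, 6)
           if counts else np.zeros((0, 0, 6), dtype=np.int64))
    return (np.asarray(chroms, dtype=object), np.asarray(positions, np.int64),
            np.asarray(refs, dtype=object), arr,
            [f"pool{i}" for i in range(n_pools)])


# ---------------------------------------------------------------------------
# FST estimators
# ---------------------------------------------------------------------------

def _wc_components(n: np.ndarray, p: np.ndarray):
    """Weir-Cockerham haploid variance components a (among) and b (within)."""
    r = n.shape[1]
    n_tot = n.sum(axis=1)
    nbar = n_tot / r
    nc = (n_tot - (n ** 2).sum(axis=1) / n_tot) / (r - 1)
    pbar = (n * p).sum(axis=1) / n_tot
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    h = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (h - s2 * (r - 1) / r) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (h - s2 * (r - 1) / r)
    return a, b


def _karlsson_components(n: np.ndarray, p: np.ndarray):
    if n.shape[1] != 2:
        raise ValueError("the karlsson estimator is defined for exactly two pools")
    h = (n / (n - 1.0)) * p * (1.0 - p)
    num = (p[:, 0] - p[:, 1]) ** 2 - h[:, 0] / n[:, 0] - h[:, 1] / n[:, 1]
    den = num + h[:, 0] + h[:, 1]
    return num, den


def fst_snp(depths, freqs, method: str = "wc"):
    """Per-SNP FST components and point estimate.

    ``depths``/``freqs`` are (n_snps, n_pools) (a single SNP may be passed as
    1-D). Returns (numerator, denominator, estimate); the estimate is NaN
    where the denominator is zero (all pools monomorphic and identical), but
    the components are always returned so windows can aggregate them as a
    ratio of sums. Per-SNP estimates may be negative.
    """
    one_snp = np.asarray(depths, dtype=float).ndim == 1
    n = np.atleast_2d(np.asarray(depths, dtype=float))
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    if n.shape != p.shape:
        raise ValueError("depths and freqs must have the same shape")
    if n.shape[1] < 2:
        raise ValueError("need at least two pools")
    if np.any(n < 2):
        raise ValueError("per-pool depth must be >= 2")
    if method == "wc":
        a, b = _wc_components(n, p)
        num, den = a, a + b
    elif method == "karlsson":
        num, den = _karlsson_components(n, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den != 0.0, num / den, np.nan)
    if one_snp:
        return float(num[0]), float(den[0]), float(est[0])
    return num, den, est


def _window_index(pos: np.ndarray, window: int) -> np.ndarray:
    return ((np.asarray(pos) - 1) // window).astype(np.int64)


def _pairs(pools, pairs=None):
    if pairs is None:
        return list(itertools.combinations(range(len(pools)), 2))
    return [tuple(pairs_i) for pairs_i in pairs]


def _window_frame(chrom, pos, window) -> pd.DataFrame:
    win = _window_index(pos, window)
    df = pd.DataFrame({"chrom": chrom, "_win": win})
    grouped = df.groupby(["chrom", "_win"], sort=True).size().rename("n_snps")
    out = grouped.reset_index()
    out["start"] = out["_win"] * window + 1
    out["end"] = (out["_win"] + 1) * window
    return out


def fst_windows(snps: SNPTable, window: int = DEFAULT_WINDOW, method: str = "wc",
                min_snps: int = DEFAULT_MIN_SNPS, pairs=None) -> pd.DataFrame:
    """Ratio-of-sums window FST for every pool pair (or the given pairs).

    Window k (1-based) spans [(k-1)*window + 1, k*window]. Windows with fewer
    than ``min_snps`` SNPs get NaN. Columns: chrom, start, end, n_snps and
    ``fst_<method>_<poolA>_<poolB>`` per pair.
    """
    out = _window_frame(snps.chrom, snps.pos, window)
    win = _window_index(snps.pos, window)
    key = pd.MultiIndex.from_arrays([snps.chrom, win])
    for (i, j) in _pairs(snps.pools, pairs):
        num, den, _ = fst_snp(snps.depths[:, [i, j]], snps.freqs[:, [i, j]], method)
        agg = pd.DataFrame({"num": num, "den": den}, index=key).groupby(level=[0, 1]).sum()
        est = agg["num"] / agg["den"]
        col = f"fst_{method}_{snps.pools[i]}_{snps.pools[j]}"
        okey = pd.MultiIndex.from_arrays([out["chrom"], out["_win"]])
        out[col] = est.reindex(okey).values
        out.loc[out["n_snps"] < min_snps, col] = np.nan
    return out.drop(columns="_win")[
        ["chrom", "start", "end", "n_snps"]
        + [c for c in out.columns if c.startswith("fst_")]]


def diversity_windows(snps: SNPTable, window: int = DEFAULT_WINDOW,
                      covered_sites=None) -> pd.DataFrame:
    """Window nucleotide diversity per pool and dxy per pool pair.

    Per variant site pi = n/(n-1) * 2 p (1-p) and
    dxy = p1 (1-p2) + p2 (1-p1); the window value is the sum over variant
    sites divided by the number of covered sites. ``covered_sites`` is the
    per-window count of sites passing the depth filters (monomorphic
    included); by default every bp of the window is assumed covered, which is
    exact for simulated data with no coverage gaps.
    """
    out = _window_frame(snps.chrom, snps.pos, window)
    win = _window_index(snps.pos, window)
    key = pd.MultiIndex.from_arrays([snps.chrom, win])
    okey = pd.MultiIndex.from_arrays([out["chrom"], out["_win"]])
    if covered_sites is None:
        out["covered_sites"] = window
    else:
        out["covered_sites"] = np.asarray(covered_sites)
    cov = out["covered_sites"].to_numpy().astype(float)

    n, p = snps.depths, snps.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, name in enumerate(snps.pools):
            pi_site = (n[:, j] / (n[:, j] - 1.0)) * 2.0 * p[:, j] * (1.0 - p[:, j])
            tot = pd.Series(pi_site, index=key).groupby(level=[0, 1]).sum()
            out[f"pi_{name}"] = tot.reindex(okey).fillna(0.0).values / cov
        for (i, j) in _pairs(snps.pools):
            dxy_site = p[:, i] * (1.0 - p[:, j]) + p[:, j] * (1.0 - p[:, i])
            tot = pd.Series(dxy_site, index=key).groupby(level=[0, 1]).sum()
            out[f"dxy_{snps.pools[i]}_{snps.pools[j]}"] = \
                tot.reindex(okey).fillna(0.0).values / cov
    mask = cov <= 0
    if mask.any():
        value_cols = [c for c in out.columns if c.startswith(("pi_", "dxy_"))]
        out.loc[mask, value_cols] = np.nan
    return out.drop(columns="_win")


def window_stats(snps: SNPTable, window: int = DEFAULT_WINDOW,
                 min_snps: int = DEFAULT_MIN_SNPS,
                 covered_sites=None) -> pd.DataFrame:
    """Both FST estimators plus pi and dxy in one window table."""
    keys = ["chrom", "start", "end", "n_snps"]
    wc = fst_windows(snps, window, "wc", min_snps)
    out = wc
    if snps.n_pools == 2:
        ka = fst_windows(snps, window, "karlsson", min_snps)
        out = out.merge(ka, on=keys)
    else:
        for (i, j) in _pairs(snps.pools):
            sub = SNPTable(chrom=snps.chrom, pos=snps.pos, major=snps.major,
                           minor=snps.minor, counts=snps.counts[:, [i, j]],
                           depths=snps.depths[:, [i, j]],
                           pools=[snps.pools[i], snps.pools[j]])
            ka = fst_windows(sub, window, "karlsson", min_snps)
            out = out.merge(ka, on=keys)
    div = diversity_windows(snps, window, covered_sites)
    return out.merge(div.drop(columns="n_snps"), on=["chrom", "start", "end"])


def bin_summary(windows: pd.DataFrame, fst_col: str,
                value_cols: Optional[Sequence[str]] = None,
                thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS) -> pd.DataFrame:
    """Median pi/dxy inside FST bins plus the genome-wide row.

    Bin membership is strict (FST > threshold), so the bins nest. The percent
    decrease column for each value is 100 * (1 - bin median / genome-wide
    median). Empty bins get NaN medians.
    """
    if value_cols is None:
        value_cols = [c for c in windows.columns if c.startswith(("pi_", "dxy_"))]
    valid = windows[windows[fst_col].notna()]
    rows = []
    genome = {c: valid[c].median() for c in value_cols}
    for thr in sorted(thresholds, reverse=True):
        sub = valid[valid[fst_col] > thr]
        row = {"bin": f">{thr}", "threshold": thr, "n_windows": len(sub)}
        for c in value_cols:
            med = sub[c].median() if len(sub) else np.nan
            row[c] = med
            row[f"{c}_pct_decrease"] = (
                100.0 * (1.0 - med / genome[c]) if genome[c] else np.nan)
        rows.append(row)
    gw = {"bin": "genome-wide", "threshold": np.nan, "n_windows": len(valid)}
    for c in value_cols:
        gw[c] = genome[c]
        gw[f"{c}_pct_decrease"] = 0.0
    rows.append(gw)
    return pd.DataFrame(rows)


def percent_decrease(genome_wide: float, bin_value: float) -> float:
    """100 * (1 - bin value / genome-wide value)."""
    return 100.0 * (1.0 - bin_value / genome_wide)


def genome_summary(windows: pd.DataFrame, fst_cols: Optional[Sequence[str]] = None,
                   top_fraction: float = 0.001) -> dict:
    """Genome-wide mean of window FST per pair and the ranked top-window table.

    The genome-wide value is the unweighted mean of window estimates (a
    genome ratio-of-sums is reported alongside by the window pipeline).
    top-k uses k = round(valid windows * fraction), at least 1; ties broken
    by (FST desc, chrom, start).
    """
    if fst_cols is None:
        fst_cols = [c for c in windows.columns if c.startswith("fst_")]
    means, tops = {}, {}
    for col in fst_cols:
        valid = windows[windows[col].notna()]
        means[col] = valid[col].mean() if len(valid) else np.nan
        k = max(1, round(len(valid) * top_fraction)) if len(valid) else 0
        ranked = valid.sort_values([col, "chrom", "start"],
                                   ascending=[False, True, True])
        tops[col] = ranked.head(k).reset_index(drop=True)
    return {"mean_fst": means, "top_windows": tops}
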