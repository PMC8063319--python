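"""Outlier-region detection: LK/FLK single-SNP tests and the Lindley local score.

The single-locus tests standardise per-SNP differentiation against its
neutral expectation:

* LK (Lewontin-Krakauer): T = (r - 1) * theta_l / mean(theta), chi-square
  with r - 1 degrees of freedom, where theta_l is the per-SNP multi-pool
  Weir-Cockerham estimate (negative estimates clamped to zero).
* FLK: the LK extension with a population kinship matrix F capturing unequal
  drift. With pooled frequency vector p, the ancestral frequency is the
  generalised least-squares estimate p0 = (1' F^-1 p)/(1' F^-1 1); under
  neutrality p - p0*1 ~ N(0, F p0 (1 - p0)), so
  T = (p - p0 1)' V^-1 (p - p0 1) is chi-square with r - 1 df. F comes from
  an outgroup-rooted population tree built from pairwise Reynolds distances.

The local score chains evidence across linked SNPs with a Lindley process
h_i = max(0, h_{i-1} + (-log10 p_i - xi)), xi fixed at the 85% quantile of
the -log10 p distribution. Excursions (maximal runs with h > 0) whose peak
exceeds a chromosome-wide threshold are called as regions. The threshold is
calibrated by Monte-Carlo: B i.i.d. resamples of the chromosome's -log10 p
values give B track maxima, and the (1 - alpha) quantile is the threshold —
under independent p-values a fraction alpha of chromosomes then produce a
false positive, while linkage inflates the realised rate, which
:func:`fpr_experiment` measures on strictly neutral simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .poolstats import FilterParams, SNPTable, filter_snps, fst_snp, fst_windows

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipModel", "LocalScoreConfig", "Region", "FprReport",
    "build_kinship", "lk_test", "flk_test", "choose_xi", "lindley_track",
    "calibrate_threshold", "call_regions", "match_regions",
    "fpr_experiment", "binomial_excess_test",
]


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipModel:
    """Outgroup-rooted three-population kinship for the FLK test.

    ``distances`` are pairwise Reynolds distances -ln(1 - theta);
    ``branch_lengths`` are root-to-tip lengths with the root at the internal
    node joining the outgroup. In the rooted 3-taxon star there is no shared
    drift, so F is diagonal in the branch lengths. ``tested`` lists the pools
    entering the test (all three by default; the outgroup can be excluded).
    """

    pools: Sequence[str]
    outgroup: str
    distances: np.ndarray       # (r, r) symmetric, zero diagonal
    branch_lengths: np.ndarray  # (r,) root-to-tip
    tested: Sequence[str] = field(default_factory=list)

    @property
    def F(self) -> np.ndarray:
        idx = [list(self.pools).index(p) for p in self.tested]
        return np.diag(self.branch_lengths[idx])

    def tested_indices(self, pools: Sequence[str]) -> list:
        return [list(pools).index(p) for p in self.tested]


def reynolds_distance(theta: float) -> float:
    """Reynolds coancestry distance D = -ln(1 - theta)."""
    return -np.log(1.0 - theta)


def build_kinship(snps: SNPTable, outgroup: str,
                  include_outgroup: bool = True) -> KinshipModel:
    """Estimate the kinship model from genome-wide SNPs.

    Pairwise theta is the two-pool Weir-Cockerham ratio of sums over all
    SNPs; distances are Reynolds -ln(1-theta); branch lengths come from the
    three-point formulas, e.g. x_A = (d_AB + d_AO - d_BO) / 2 with the root
    at the internal node. Raises if any branch is non-positive (F would be
    singular) — typically a sign of too few or undiverged SNPs.
    """
    pools = list(snps.pools)
    r = len(pools)
    if r < 3:
        raise ValueError("kinship needs at least three pools (two tested + outgroup)")
    if outgroup not in pools:
        raise ValueError(f"outgroup {outgroup!r} not among pools {pools}")
    if snps.n_snps < 100:
        raise ValueError("kinship estimation needs at least 100 SNPs")
    D = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            num, den, _ = fst_snp(snps.depths[:, [i, j]], snps.freqs[:, [i, j]], "wc")
            theta = num.sum() / den.sum()
            D[i, j] = D[j, i] = reynolds_distance(theta)
    branch = _three_point_branches(D, pools, outgroup)
    if np.any(branch <= 0):
        raise ValueError(
            "non-positive branch length: kinship matrix would be singular; "
            "use more (or more divergent) SNPs")
    tested = pools if include_outgroup else [p for p in pools if p != outgroup]
    return KinshipModel(pools=pools, outgroup=outgroup, distances=D,
                        branch_lengths=branch, tested=tested)


def _three_point_branches(D: np.ndarray, pools, outgroup) -> np.ndarray:
    if len(pools) != 3:
        raise ValueError("the three-point root solution requires exactly 3 pools")
    a, b = [i for i, p in enumerate(pools) if p != outgroup]
    o = pools.index(outgroup)
    x = np.zeros(3)
    x[a] = (D[a, b] + D[a, o] - D[b, o]) / 2.0
    x[b] = (D[a, b] + D[b, o] - D[a, o]) / 2.0
    x[o] = (D[a, o] + D[b, o] - D[a, b]) / 2.0
    return x


# ---------------------------------------------------------------------------
# Single-SNP tests
# ---------------------------------------------------------------------------

def lk_test(snps: SNPTable) -> pd.DataFrame:
    """Lewontin-Krakauer test per SNP.

    T = (r - 1) * theta_l / mean(theta) with the multi-pool Weir-Cockerham
    theta per SNP; negative estimates are clamped to zero before scaling and
    the mean is taken over SNPs with a defined estimate. p-values from the
    upper tail of chi-square with r - 1 df.
    """
    _, _, theta = fst_snp(snps.depths, snps.freqs, "wc")
    defined = np.isfinite(theta)
    clamped = np.where(theta < 0, 0.0, theta)
    mean_theta = clamped[defined].mean() if defined.any() else np.nan
    if not np.isfinite(mean_theta) or mean_theta <= 0:
        raise ValueError("mean per-SNP theta is not positive; LK undefined")
    df = snps.n_pools - 1
    T = np.where(defined, df * clamped / mean_theta, np.nan)
    p = np.where(defined, stats.chi2.sf(T, df), np.nan)
    p = np.where(defined, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return pd.DataFrame({"chrom": snps.chrom, "pos": snps.pos,
                         "T_LK": T, "p_LK": p})


def flk_test(snps: SNPTable, model: KinshipModel) -> pd.DataFrame:
    """FLK test per SNP against the kinship model.

    SNPs whose estimated ancestral frequency p0 is 0 or 1 are dropped
    (NaN statistics): the null covariance V = F p0 (1 - p0) is singular there.
    """
    idx = model.tested_indices(snps.pools)
    p = snps.freqs[:, idx]
    F = model.F
    Finv = np.linalg.inv(F)
    ones = np.ones(len(idx))
    w = Finv @ ones / (ones @ Finv @ ones)   # GLS weights for p0
    p0 = np.clip(p @ w, 0.0, 1.0)
    resid = p - p0[:, None]
    # V^-1 = F^-1 / (p0 (1-p0)); quadratic form vectorised over SNPs
    quad = np.einsum("si,ij,sj->s", resid, Finv, resid)
    h0 = p0 * (1.0 - p0)
    ok = h0 > 0
    T = np.where(ok, quad / np.where(ok, h0, 1.0), np.nan)
    df = len(idx) - 1
    pval = np.where(ok, stats.chi2.sf(T, df), np.nan)
    pval = np.where(ok, np.clip(pval, np.finfo(float).tiny, 1.0), np.nan)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("flk_test: dropped %d SNPs with boundary p0", n_drop)
    return pd.DataFrame({"chrom": snps.chrom, "pos": snps.pos,
                         "T_FLK": T, "p_FLK": pval, "p0": p0})


# ---------------------------------------------------------------------------
# Local score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalScoreConfig:
    """Tuning of the Lindley local score and its threshold calibration."""

    xi_quantile: float = 0.85
    alpha: float = 0.05
    B: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not (0 < self.xi_quantile < 1):
            raise ValueError("xi_quantile must be in (0, 1)")


@dataclass(frozen=True)
class Region:
    """One significant local-score excursion."""

    chrom: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    peak: float
    peak_index: int
    peak_bp: int

    def overlaps(self, other: "Region") -> bool:
        return (self.chrom == other.chrom
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)


def choose_xi(pvalues, quantile: float = 0.85) -> float:
    """xi = the empirical ``quantile`` of the -log10 p distribution.

    The offset must lie between the mean and the maximum of -log10 p for the
    Lindley process to have negative drift yet retain power; this is asserted.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    scores = -np.log10(p)
    xi = float(np.quantile(scores, quantile))
    if not (scores.mean() - 1e-12 <= xi <= scores.max() + 1e-12):
        raise AssertionError(
            f"xi={xi} outside [mean, max] = [{scores.mean()}, {scores.max()}]")
    return xi


def lindley_track(pvalues, xi: float) -> np.ndarray:
    """Lindley process h_i = max(0, h_{i-1} + (-log10 p_i - xi)), h_0 = 0.

    ``pvalues`` must be ordered by genomic position within one chromosome.
    Computed via the reflection identity h = S - min(0, running_min(S)) with
    S the cumulative sum of scores, so the whole track is vectorised.
    """
    p = np.asarray(pvalues, dtype=float)
    scores = -np.log10(p) - xi
    S = np.cumsum(scores)
    floor = np.minimum.accumulate(np.minimum(S, 0.0))
    return S - floor


def _track_maxima(scores_matrix: np.ndarray) -> np.ndarray:
    """Max of the Lindley track for each row of per-SNP scores."""
    S = np.cumsum(scores_matrix, axis=1)
    floor = np.minimum.accumulate(np.minimum(S, 0.0), axis=1)
    return (S - floor).max(axis=1)


def calibrate_threshold(pvalues, xi: float, alpha: float = 0.05, B: int = 200,
                        seed=0) -> float:
    """Chromosome-wide significance threshold for the local score.

    Monte-Carlo: B i.i.d. resamples (with replacement) of the chromosome's
    -log10 p values, each of the chromosome's length; the threshold is the
    empirical (1 - alpha) quantile of the B track maxima. A zero threshold
    suppresses all calls downstream.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    p = np.asarray(pvalues, dtype=float)
    scores = -np.log10(p) - xi
    rng = np.random.default_rng(seed)
    n = len(scores)
    # chunk the B x n resample matrix to bound memory on long chromosomes
    maxima = np.empty(B)
    chunk = max(1, int(5e7) // max(n, 1))
    for b0 in range(0, B, chunk):
        b1 = min(B, b0 + chunk)
        draws = rng.choice(scores, size=(b1 - b0, n), replace=True)
        maxima[b0:b1] = _track_maxima(draws)
    return float(np.quantile(maxima, 1.0 - alpha))


def call_regions(track: np.ndarray, threshold: float, positions,
                 chrom: str = "chr1") -> list:
    """Regions = excursions (maximal runs with h > 0) whose peak >= threshold.

    Bounds run from the first SNP of the excursion to the last SNP before the
    track returns to zero (or the chromosome end); the peak is the first
    argmax within the excursion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (zero suppresses all calls)")
    h = np.asarray(track, dtype=float)
    positions = np.asarray(positions)
    regions = []
    pos_mask = h > 0
    if not pos_mask.any():
        return regions
    # run starts/ends of the h > 0 excursions
    diff = np.diff(pos_mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0])
    if pos_mask[0]:
        starts.insert(0, 0)
    if pos_mask[-1]:
        ends.append(len(h) - 1)
    for s, e in zip(starts, ends):
        seg = h[s:e + 1]
        peak = float(seg.max())
        if peak >= threshold:
            k = s + int(np.argmax(seg))
            regions.append(Region(
                chrom=chrom, start_index=s, end_index=e,
                start_bp=int(positions[s]), end_bp=int(positions[e]),
                peak=peak, peak_index=k, peak_bp=int(positions[k])))
    return regions


def scan_chromosome(pvalues, positions, xi: float, config: LocalScoreConfig,
                    chrom: str, seed) -> tuple:
    """Threshold calibration + region calling for one chromosome."""
    threshold = calibrate_threshold(pvalues, xi, config.alpha, config.B, seed)
    track = lindley_track(pvalues, xi)
    regions = (call_regions(track, threshold, positions, chrom)
               if threshold > 0 else [])
    return regions, threshold


def match_regions(regions_a: Sequence[Region], regions_b: Sequence[Region]) -> dict:
    """Match two region sets by bp overlap.

    Returns counts of regions found by both (counted once per union element),
    and by exactly one. The union size is matched + only_a + only_b, where
    overlapping a/b regions are greedily paired in genomic order.
    """
    used_b = set()
    matched = 0
    for ra in regions_a:
        for k, rb in enumerate(regions_b):
            if k in used_b:
                continue
            if ra.overlaps(rb):
                used_b.add(k)
                matched += 1
                break
    only_a = len(regions_a) - matched
    only_b = len(regions_b) - len(used_b)
    union = matched + only_a + only_b
    return {"matched": matched, "only_a": only_a, "only_b": only_b, "union": union}


# ---------------------------------------------------------------------------
# False-positive-rate experiment
# ---------------------------------------------------------------------------

@dataclass
class FprReport:
    """Significant-region counts over neutral pseudo-genome replicates.

    FPR is significant regions divided by (genomes x chromosomes);
    ``discordance`` is the fraction of the region union significant under
    exactly one of FLK/LK.
    """

    n_genomes: int
    n_chrom: int
    regions_flk: int
    regions_lk: int
    discordant: int
    region_union: int
    mean_pair_fst: float
    per_genome: list = field(default_factory=list)

    @property
    def fpr_flk(self) -> float:
        return self.regions_flk / (self.n_genomes * self.n_chrom)

    @property
    def fpr_lk(self) -> float:
        return self.regions_lk / (self.n_genomes * self.n_chrom)

    @property
    def regions_per_genome_flk(self) -> float:
        return self.regions_flk / self.n_genomes

    @property
    def regions_per_genome_lk(self) -> float:
        return self.regions_lk / self.n_genomes

    @property
    def discordance(self) -> float:
        return self.discordant / self.region_union if self.region_union else 0.0

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes, "n_chrom": self.n_chrom,
            "regions_flk": self.regions_flk, "regions_lk": self.regions_lk,
            "fpr_flk": self.fpr_flk, "fpr_lk": self.fpr_lk,
            "regions_per_genome_flk": self.regions_per_genome_flk,
            "regions_per_genome_lk": self.regions_per_genome_lk,
            "discordant_regions": self.discordant,
            "region_union": self.region_union,
            "discordance": self.discordance,
            "mean_pair_fst": self.mean_pair_fst,
        }


def scan_genome(snps: SNPTable, model: KinshipModel, config: LocalScoreConfig,
                seed) -> dict:
    """FLK + LK local-score scan of one (pseudo-)genome.

    xi is chosen genome-wide per statistic; thresholds are calibrated per
    chromosome. Returns per-statistic region lists and per-chromosome
    discordance counts.
    """
    flk = flk_test(snps, model)
    lk = lk_test(snps)
    ok_flk = flk["p_FLK"].notna().to_numpy()
    ok_lk = lk["p_LK"].notna().to_numpy()
    xi_flk = choose_xi(flk.loc[ok_flk, "p_FLK"], config.xi_quantile)
    xi_lk = choose_xi(lk.loc[ok_lk, "p_LK"], config.xi_quantile)
    ss = np.random.SeedSequence(entropy=int(seed))
    regions = {"flk": [], "lk": []}
    discordant = union = 0
    chroms = pd.unique(snps.chrom)
    child_seeds = ss.generate_state(2 * len(chroms)) % (2**31 - 1)
    for ci, chrom in enumerate(chroms):
        m = snps.chrom == chrom
        r_flk, _ = scan_chromosome(
            flk.loc[m & ok_flk, "p_FLK"].to_numpy(),
            flk.loc[m & ok_flk, "pos"].to_numpy(),
            xi_flk, config, str(chrom), int(child_seeds[2 * ci]))
        r_lk, _ = scan_chromosome(
            lk.loc[m & ok_lk, "p_LK"].to_numpy(),
            lk.loc[m & ok_lk, "pos"].to_numpy(),
            xi_lk, config, str(chrom), int(child_seeds[2 * ci + 1]))
        regions["flk"].extend(r_flk)
        regions["lk"].extend(r_lk)
        mm = match_regions(r_flk, r_lk)
        discordant += mm["only_a"] + mm["only_b"]
        union += mm["union"]
    return {"regions": regions, "discordant": discordant, "union": union,
            "xi": {"flk": xi_flk, "lk": xi_lk},
            "flk_table": flk, "lk_table": lk}


def fpr_experiment(sim_config, n_genomes: int, scan_config: LocalScoreConfig,
                   seed: int, engine: str = "msprime",
                   filter_params: Optional[FilterParams] = None,
                   outgroup: Optional[str] = None,
                   window: int = 100_000, progress: bool = False) -> FprReport:
    """Estimate the local score's type-I error on strictly neutral simulations.

    For each pseudo-genome: simulate, pool-sample, filter, estimate kinship,
    run FLK and LK local-score scans (genome-wide xi, per-chromosome
    thresholds at alpha), and count significant regions. Also accumulates the
    mean pairwise window Weir-Cockerham FST across genomes.
    """
    from .sim import simulate_pseudo_genome

    if filter_params is None:
        filter_params = FilterParams(
            maf_min=sim_config.maf_min,
            depth_min=sim_config.depth_min, depth_max=sim_config.depth_max)
    master = np.random.SeedSequence(entropy=int(seed))
    genome_seeds = master.generate_state(3 * n_genomes) % (2**31 - 1)
    total_flk = total_lk = discordant = union = 0
    fst_means = []
    per_genome = []
    for g in range(n_genomes):
        ds, _truth = simulate_pseudo_genome(sim_config, int(genome_seeds[3 * g]),
                                            engine=engine)
        snps = filter_snps(ds, filter_params)
        og = outgroup if outgroup is not None else snps.pools[-1]
        model = build_kinship(snps, og)
        result = scan_genome(snps, model, scan_config, int(genome_seeds[3 * g + 1]))
        n_flk = len(result["regions"]["flk"])
        n_lk = len(result["regions"]["lk"])
        total_flk += n_flk
        total_lk += n_lk
        discordant += result["discordant"]
        union += result["union"]
        wins = fst_windows(snps, window=window, method="wc")
        pair_cols = [c for c in wins.columns if c.startswith("fst_wc_")]
        fst_means.append(np.nanmean([wins[c].mean() for c in pair_cols]))
        per_genome.append({"genome": g, "regions_flk": n_flk, "regions_lk": n_lk,
                           "mean_pair_fst": fst_means[-1]})
        if progress:
            logger.info("genome %d/%d: FLK=%d LK=%d fst=%.3f",
                        g + 1, n_genomes, n_flk, n_lk, fst_means[-1])
    return FprReport(
        n_genomes=n_genomes, n_chrom=sim_config.n_chrom,
        regions_flk=total_flk, regions_lk=total_lk,
        discordant=discordant, region_union=union,
        mean_pair_fst=float(np.mean(fst_means)), per_genome=per_genome)


def binomial_excess_test(k_observed: int, n_chrom: int, p_rate: float) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p) by direct summation.

    The null: the empirical data yield no more significant regions than the
    neutral simulations' false-positive rate predicts.
    """
    if not (0 <= p_rate <= 1):
        raise ValueError("p_rate must be in [0, 1]")
    if k_observed < 0 or n_chrom < 0 or k_observed > n_chrom:
        raise ValueError("need 0 <= k_observed <= n_chrom")
    ks = np.arange(k_observed, n_chrom + 1)
    return float(np.minimum(1.0, stats.binom.pmf(ks, n_chrom, p_rate).sum()))
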