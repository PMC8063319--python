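# Methods

## The neutral model

`poolscan.sim` implements a discrete-generation Wright–Fisher model with
three phases:

1. **Burn-in.** A single panmictic deme of `n_anc` diploids starts
   monomorphic and evolves for `t_burn` generations. Starting monomorphic
   (rather than at mutation–drift equilibrium) is deliberate: with the
   default `t_burn = 1000` and `n_anc = 1000` the ancestral deme reaches
   only 1 − e^(−t/2N) ≈ 39% of equilibrium diversity at the split, which
   shapes the ratio of ancestral (shared, high-F_ST) to post-split
   (private, low-F_ST) variation in everything downstream.
2. **Split.** The deme founds `n_demes` isolated demes of `n_deme` diploids
   (each founded by one Wright–Fisher generation drawn from the ancestral
   gene pool), which then drift with no migration for `t_split` generations.
3. **Mutation and recombination.** Neutral infinite-sites mutation at rate
   `mu` per bp per generation on a continuous chromosome (a draw hitting an
   occupied position is redrawn; no back mutation) and uniform crossover at
   `rec` per bp per generation. Defaults `mu = 2e-7`, `rec = 1.5e-8` on
   75 Mb chromosomes (≈1.1 Morgan); 30 chromosomes form a pseudo-genome.

Two engines expose identical contracts:

* `engine="forward"` — individual-based forward simulation; the reference
  implementation, exact but slow, used at small sizes in tests.
* `engine="msprime"` (default) — backward-in-time simulation with msprime's
  discrete-time Wright–Fisher (DTWF) model. DTWF rather than the Hudson
  coalescent because whole demes are sampled (n = 2N chromosome copies,
  far outside the n ≪ N regime). The monomorphic founding is emulated by
  shrinking the ancestral deme to a single diploid at time
  `t_split + t_burn`, which forces complete coalescence there, so no
  variation predates the burn-in. Mutations use msprime's binary
  infinite-sites model on a continuous genome; positions are floored to
  1-based integers and the rare collisions dropped.

Engine equivalence is asserted empirically: heterozygosity and
ratio-of-sums F_ST from the two engines agree within 3 Monte-Carlo
standard errors at test scale, and λ-scaled runs (λ ∈ {5, 10}) agree with
λ = 1 runs of the same population-scaled parameters.

### Scaling

`scale_config(config, λ)` maps N → N/λ, t → t/λ, μ → λμ, r → λr. This
preserves 4Nμ, 4Nr and t/2N — hence per-bp SNP density, heterozygosity,
F_ST and the bp scale of linkage disequilibrium — while cutting runtime by
~λ². Scaling below 20 diploids per deme is refused (discreteness of drift
would no longer be comparable). The desk profile used throughout the tests
and the acceptance script is λ = 10 with 2 Mb chromosomes and 30
chromosomes per pseudo-genome; at these sizes one pseudo-genome simulates,
filters and scans in ~7 s on one CPU, and the 20-genome calibration study
runs in ~2.5 minutes.

### Pool sequencing

Read depth is drawn independently per site and per pool from a normal
(`depth_mean = 23`, `depth_sd = 5`) rounded to the nearest integer and
rejection-truncated to [`depth_min = 15`, `depth_max = 50`] after
rounding; the derived-read count is Binomial(depth, true frequency). Depth
per site (rather than per chromosome) matches the site-to-site coverage
variation of real pool-seq; the choice is isolated in `sample_pool` and
easily switched. The global MAF filter (pooled read counts across pools,
MAF > 0.05 by default) is applied inside `simulate_pseudo_genome`, mirroring
the SNP-retention rule of the analysis modules.

What the generator deliberately does **not** emulate: sequencing error and
PCR duplicates, indels (hence no indel-proximity masking), reference bias
or mapping artefacts, selection, migration, unequal deme sizes, and
non-uniform recombination. Tests passing on this generator therefore
validate the statistical machinery on clean neutral input; they do not
certify behaviour under real-data artefacts.

## Window statistics

Pooled read counts carry no genotype pairing, so each pool is treated as a
haploid sample of size n_i = read depth at the site (standard pool-seq
practice; the finite number of pooled chromosomes is ignored). The
Weir–Cockerham estimator is used in its two-level haploid form: with
n̄ = Σn_i/r, n_c = (Σn_i − Σn_i²/Σn_i)/(r−1), p̄ = Σn_i p̂_i/Σn_i and
s² = Σn_i(p̂_i − p̄)²/((r−1)n̄),

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²(r−1)/r) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²(r−1)/r ]
    θ̂ = a / (a + b)

Per-SNP estimates may be negative; hand-checkable anchors are θ̂ = 1 at a
fixed difference and θ̂ = −1/(n̄−1) at identical frequencies. The Karlsson
two-pool estimator is provided for cross-checking; the two agree in window
rank (Spearman ρ > 0.95 on simulated data).

Windows are non-overlapping, 1-based, `window = 100000` bp by default
(window k spans [(k−1)w+1, kw]); window F_ST is the ratio of summed
components, and windows with fewer than `min_snps = 10` SNPs are reported
with missing F_ST (the cutoff is a package choice; it is configurable).
Genome-wide F_ST per pair is summarised as the unweighted mean of window
estimates. π uses the depth-corrected per-site heterozygosity
n/(n−1)·2p̂(1−p̂); window π and d_xy divide the sum over variant sites by
the count of covered sites (all window bp by default, exact for simulated
data; real data should pass per-window covered-site counts). F_ST-bin
summaries use strict thresholds (F_ST > 0.2/0.3/0.4/0.5), report median π
and d_xy per bin, and the percent decrease 100·(1 − bin/genome-wide).

## LK, FLK and the kinship matrix

Pairwise Reynolds distances D = −ln(1 − θ̂) (θ̂ the two-pool ratio of sums
over all SNPs) are fitted to the rooted 3-taxon tree by the three-point
formulas, with the root at the internal node joining the outgroup. In that
topology no two tested populations share a root-to-tip branch, so the
kinship matrix F is diagonal in the branch lengths. All three populations
(outgroup included) enter the tests by default (χ² df = 2, matching a
three-deme simulation design); an exclude-outgroup mode (df = 1) is
available. Estimation fails loudly if any branch length is non-positive
(F would be singular).

FLK: p̂₀ = (1ᵀF⁻¹p̂)/(1ᵀF⁻¹1) clamped to [0,1]; V = F·p̂₀(1−p̂₀);
T = (p̂ − p̂₀1)ᵀV⁻¹(p̂ − p̂₀1), upper-tail χ² with r−1 df. SNPs with
boundary p̂₀ are dropped with a logged count. Under ideal conditions (true
frequencies, known star-topology F) the statistic is verified to follow
χ²₂ by a Kolmogorov–Smirnov test at 10⁴ loci. LK: T = (r−1)·θ̂/mean(θ̂)
with negative per-SNP θ̂ clamped to zero before scaling and the mean taken
over SNPs with a defined estimate (clamped values included — a documented
convention, as the classical statistic does not specify pooled-data
handling).

Note that F models drift variance only; binomial read-sampling noise is
not added to V. At depth ~23 this inflates T_FLK mildly and uniformly; the
local-score calibration below absorbs distributional misfit because both
ξ and the thresholds derive from the observed p-value distribution.

## Local score and threshold calibration

Scores are −log₁₀p − ξ with ξ the empirical 85% quantile of −log₁₀p,
computed genome-wide per statistic (a per-chromosome mode exists behind a
flag). ξ must lie between the mean and the maximum of −log₁₀p, which is
asserted. The Lindley track h_i = max(0, h_{i−1} + score_i) is computed by
the reflection identity h = S − min(0, running min S), so tracks and the
B-resample calibration are fully vectorised. A region is a maximal h > 0
excursion whose peak reaches the chromosome's threshold; bounds run from
the excursion's first SNP to the last SNP before h returns to zero, the
peak is the first argmax.

The chromosome-wide threshold is the (1−α) quantile of track maxima over
B i.i.d. resamples (with replacement, chromosome length) of that
chromosome's −log₁₀p values; defaults α = 0.05, B = 200. This definition
makes the advertised contract — a fraction α of chromosomes produce a
false positive — hold exactly under independent p-values, which the test
suite verifies to within 3 binomial standard errors, while leaving linkage
free to inflate the realised rate. An analytic extreme-value approximation
of the threshold is deliberately out of scope; the Monte-Carlo definition
is self-contained and assumption-light.

## The false-positive-rate study

`fpr_experiment` simulates strictly neutral pseudo-genomes, runs the full
FLK and LK local-score scans, and reports: significant regions per genome,
the per-chromosome type-I error (regions ÷ genomes × chromosomes), and the
FLK/LK discordance — the fraction of the bp-overlap-matched region union
significant under exactly one statistic. With the default design
(λ = 10-scaled: ancestral 1000 diploids for 1000 generations, three demes
of 1000 isolated for 2500 generations) the simulated divergence is high —
mean pairwise 100 kb-window F_ST ≈ 0.57, since t/2N = 1.25 of isolation
drift puts ancestral variants near F_ST ≈ 0.7 — and the realised
per-chromosome type-I error of the α = 0.05 scan is larger than 100%
(several significant regions per chromosome; see the acceptance outputs).
The inflation is the central methodological point: it is produced entirely
by linkage and shared drift, as the identical machinery holds the rate at
α under independent p-values. Its magnitude grows with the divergence level
and with the LD-block-to-chromosome-length ratio, so desk-scale runs
(0.3 Morgan chromosomes) sit above what full-length (≈1.1 Morgan)
chromosomes would give; both far exceed the nominal α.

`binomial_excess_test(k, n, p)` supplies the follow-up decision rule: the
exact one-sided tail P(X ≥ k) for observing k significant chromosomes (or
regions) among n when the neutral rate is p.

## Enrichment

Genes (GFF3, 1-based inclusive; any-bp overlap) in windows above an F_ST
threshold form the target set; the exact hypergeometric upper tail
P(X ≥ b) of drawing b term-carrying genes in n target draws from an
N-gene universe with B carriers tests each term of a flat gene→term map.
"Include" mode keeps target genes in the background universe; "exclude"
removes them (the universe is then the disjoint union of target and
target-free background). Raw p ≤ 0.001 is the significance gate;
Benjamini–Hochberg q-values are reported for convenience. No
ontology-graph propagation or ranked-list (mHG) testing is performed.

## Numerical and degenerate-input conventions

* Monomorphic-in-all-pools sites: F_ST components 0/0 → estimate NaN,
  components still aggregated.
* Negative LK θ̂ → clamped to 0 (T = 0, p = 1).
* FLK p̂₀ ∈ {0, 1} → SNP dropped from testing (logged).
* p-values clipped into (tiny, 1] before logs.
* Zero covered sites in a window → missing π/d_xy; < `min_snps` SNPs →
  missing window F_ST.
* Threshold ≤ 0 (all resampled tracks flat) → no regions called.
* Peak ties → first index; region matching is greedy in genomic order.
* All Monte-Carlo results are reproducible from (config, seed); every
  internal seed is spawned deterministically below 2³¹.

## Known limitations

* The pool-size correction for the finite number of pooled chromosomes
  (e.g. NPStat-style) is not applied; read depth is the sample size.
* FLK ignores read-sampling noise in V (see above).
* The exclude-outgroup FLK mode tests two populations with df = 1;
  kinship still requires all three for rooting.
* Enrichment assumes the term map is already propagated/flattened.
* The forward engine is O(generations × deme size × segregating sites)
  and intended for validation, not production runs.
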