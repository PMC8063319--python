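# poolscan

Pool-seq divergence scans with simulation-calibrated outlier detection.

`poolscan` is for population geneticists analysing pooled whole-genome
resequencing ("pool-seq") of a few diverging populations — for example
sympatric ecomorphs of a fish species — who want to (i) quantify genomic
differentiation in windows, (ii) search for outlier regions with
single-locus tests chained by a local score, (iii) know how often that
outlier machinery fires on purely neutral data, and (iv) ask what the genes
in the most divergent windows do.

The pipeline starts from PoPoolation2-style `sync` tables (one row per
site, per-pool `A:T:C:G:N:del` read counts) and provides four modules:

* **`poolscan.sim`** — a neutral Wright–Fisher model: one ancestral deme of
  *N* diploids evolves from a monomorphic start for *t*<sub>burn</sub>
  generations, splits into three isolated demes that drift for
  *t*<sub>split</sub> generations under infinite-sites mutation (μ per bp)
  and uniform recombination (*r* per bp); pool sequencing draws per-site
  depths from a truncated normal and binomial read counts. A scaling knob λ
  maps (N, t, μ, r) → (N/λ, t/λ, λμ, λr), preserving 4Nμ, 4Nr and t/2N for
  fast desk-scale runs. Two interchangeable engines: an individual-based
  forward simulator (reference) and an msprime DTWF backend (default,
  orders of magnitude faster).
* **`poolscan.poolstats`** — SNP filtering (biallelic, global MAF, minor-copy
  and per-pool depth bounds) and window statistics in non-overlapping 100 kb
  windows: F<sub>ST</sub> by the Weir–Cockerham (1984) haploid estimator,
  θ̂ = a/(a+b) aggregated as a ratio of sums, and by the Karlsson et al.
  (2007) two-pool estimator; nucleotide diversity
  π = n/(n−1)·2p̂(1−p̂) and absolute divergence
  d<sub>xy</sub> = p̂₁(1−p̂₂) + p̂₂(1−p̂₁); F<sub>ST</sub>-bin summaries and
  genome-level reports with top-0.1% window tables.
* **`poolscan.scan`** — per-SNP LK (Lewontin–Krakauer) and FLK tests. FLK
  models the pooled frequency vector p̂ around a GLS ancestral estimate p̂₀
  with covariance F·p̂₀(1−p̂₀), where the kinship matrix F is diagonal in
  the root-to-tip branch lengths of an outgroup-rooted population tree
  built from pairwise Reynolds distances −ln(1−θ̂). Evidence is chained
  across linked SNPs by a Lindley process
  h<sub>i</sub> = max(0, h<sub>i−1</sub> + (−log₁₀p<sub>i</sub> − ξ)) with
  ξ the 85% quantile of −log₁₀p; excursions are significant when their peak
  exceeds a chromosome-wide threshold calibrated by Monte-Carlo resampling
  of the observed p-value distribution at error rate α. A false-positive
  experiment runs the whole scan on strictly neutral pseudo-genomes and
  reports regions per genome, per-chromosome type-I error and FLK/LK
  discordance, plus an exact binomial test for excess empirical calls.
* **`poolscan.enrichment`** — maps genes (GFF3) onto qualifying windows and
  tests term enrichment with the exact hypergeometric upper tail
  (target-vs-background, include/exclude modes), Benjamini–Hochberg
  q-values, and a raw p ≤ 0.001 significance gate.

## Worked example

Simulate a small three-deme dataset (4 chromosomes of 1 Mb; deme size 50,
125 generations of isolation), scan it, and call local-score regions:

```bash
cat > tiny.yaml <<'YAML'
n_anc: 50
t_burn: 100
n_demes: 3
n_deme: 50
t_split: 125
chrom_len: 1000000
mu: 4.0e-6
rec: 3.0e-7
n_chrom: 4
depth_mean: 23.0
depth_sd: 5.0
depth_min: 15
depth_max: 50
maf_min: 0.05
scale: 1.0
seed: 0
YAML

poolscan simulate --config tiny.yaml --seed 7 --out demo
poolscan fst --sync demo.sync --out windows.tsv
poolscan flk --sync demo.sync --outgroup pool2 --out flk.tsv
poolscan localscore --pvalues flk.tsv --column p_FLK --seed 3 --out regions.tsv
```

`demo.sync` holds 16,450 MAF-filtered SNPs with per-pool read counts:

```
chr1	17	A	26:0:0:0:0:0	7:11:0:0:0:0	30:0:0:0:0:0
chr1	264	A	18:0:0:0:0:0	0:17:0:0:0:0	31:0:0:0:0:0
```

`windows.tsv` gives per-window SNP counts and both F<sub>ST</sub>
estimators (here the first 100 kb windows of chr1; with t/2N = 1.25 of
drift these demes are strongly diverged, mean pairwise window
F<sub>ST</sub> ≈ 0.585):

```
chrom	start	end	n_snps	fst_wc_pool0_pool1	fst_karlsson_pool0_pool1
chr1	1	100000	412	0.5846986926563980	0.5853027861536787
chr1	100001	200000	418	0.6674870407835085	0.6701650080029870
chr1	200001	300000	364	0.7793451916279108	0.7812261889493192
```

`regions.tsv` lists the significant Lindley excursions of the FLK scan —
all 11 are false positives, since the simulation is strictly neutral:

```
chrom	start_bp	end_bp	peak	peak_bp	threshold	statistic
chr1	148198	150755	1.7472869182656723	150409	1.5928490960917540	p_FLK
chr1	242095	247362	2.0313925203498115	246434	1.5928490960917540	p_FLK
chr1	831359	834577	1.7800935878606197	833103	1.5928490960917540	p_FLK
```

That excess of neutral calls is the point of the calibration module: under
linked data the nominal chromosome-wide α of the local score badly
understates the realised false-positive rate (see `docs/methods.md`).

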