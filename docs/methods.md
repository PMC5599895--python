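# Methods

This note documents the statistical model behind `methylseed`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerically delicate choices.

## Data model

The atomic observation is a strand-specific cytosine with a trinucleotide
context and (methylated, total) read-call counts, carried in allc-style
tables (chromosome, 1-based position, strand, context 3-mer, mc, cov).
Internally every coordinate is 0-based half-open; allc positions are
converted on ingestion and back on export, so round-trips are bit-exact.
Context classification is total on {A,C,G,T}³ with first base C: CG iff the
second base is G, CHG iff the second base is in {A,C,T} and the third is G,
CHH otherwise; records with N in positions 2–3 are unclassifiable and are
dropped with a logged count. Chromosome names are matched by exact string
equality; a normalization map ("1" → "Chr1") is available at read time.
Strands are kept separate by default — symmetric-CG dyad merging is provided
(`merge_symmetric_cg`) but off, since region-level weighted methylation is
invariant to it (same count sums).

## Weighted methylation

The level of a region is Σmc/Σcov over its cytosines of one context, both
strands. This coverage-weighted form is additive over disjoint regions and
invariant to uniform count duplication; it is *not* the mean of site ratios,
which over-weights shallow sites. Regions with zero covered cytosines are
undefined and propagated as NaN, never 0 — imputing 0 would fabricate
hypomethylation exactly where data are absent. Levels are not corrected for
bisulfite non-conversion by default (the rate is reported as QC:
Σmc/Σcov over all contexts on the naturally unmethylated control
chromosome); an opt-in correction `(mc − r·cov)/((1−r)·cov)`, floored at 0,
is available. Chromosome-bin profiles use fixed `[k·B, (k+1)·B)` bins
(default B = 100 kb) with per-bin weighted levels, undefined bins reported
as missing.

## The site test and its null

A site with per-sample counts (mᵢ, nᵢ) is scored by the root-mean-square
divergence of the observed 2×S frequency table from its homogeneity
expectation, which reduces to `T = sqrt(meanᵢ dᵢ²)`, `dᵢ = (mᵢ − p̂nᵢ)/N`.
The null re-partitions the N pooled read labels into groups of the observed
sizes — the natural exchangeable null for count tables, exactly
(multivariate) hypergeometric; drawing it is vectorized over sites and
permutations as sequential hypergeometric draws. The reported per-site
p-value is `(1 + #{perm ≥ obs})/(1 + P)` (add-one, so p ≥ 1/(P+1));
comparisons use an absolute tolerance of 1e−12 so that mathematically tied
statistics computed from integers count as ties. The coverage rule
("≥ 5 reads") is enforced in *every* compared sample: the statistic is
undefined for an empty sample and the stricter reading is reproducible.
Multi-sample series are tested jointly in one S-sample table, not pairwise.

## Empirical FDR: thresholding the statistic, not the Monte-Carlo p

Each permutation applied across all sites constitutes one fully permuted
dataset. For a cutoff c on the statistic,

    FDR(c) = ( #{(site, perm): T_perm ≥ c} / P ) / #{site: T_obs ≥ c},

and sites at or above the smallest cutoff with FDR ≤ 0.01 are DMSs.
The cutoff grid runs over the observed statistics. The design choice that
matters here: the threshold is applied to the *statistic*, not to the
per-site Monte-Carlo p-value. The Monte-Carlo p is floored at 1/(P+1), so
on a mostly-null dataset any p-cutoff admits at least n_sites/(P+1)
expected null discoveries per permuted dataset — with 10⁴ sites and 1000
permutations that is ≥ 10 false discoveries at the most stringent cutoff,
making an FDR of 0.01 unreachable regardless of signal strength. Statistic
cutoffs have no such floor: null exceedances of a deep cutoff can be
arbitrarily rare (fractional per permuted dataset), which is what makes
genome-scale calling at FDR 0.01 possible at all. Benjamini–Hochberg on the
Monte-Carlo p-values is available as an alternative (`fdr_method="bh"`).

This estimator is conservative when effect sites have much higher pooled
methylation than the null background: their own permuted statistics are the
largest contributions to the numerator, so the selected cutoff sits well
above the largest truly-null statistic (measured precision on planted data
is ~1.0). A consequence worth stating plainly: with two samples at mean
coverage 20, a true-rate difference of 0.4 gives per-site exact permutation
p-values of ~0.003–0.03, so no threshold choice can flag ≥ 75% of such
sites at FDR 0.01 on a genome-scale background — even an oracle cutoff at
the maximum null statistic yields per-site power ≈ 0.7. Region-level
sensitivity for 6-site DMRs at that effect size is therefore ~0.3–0.5, and
reaching sensitivity ≥ 0.8 requires either stronger per-site effects
(≈ 0.55 difference at this coverage, where measured sensitivity is 0.86 and
precision 0.98) or deeper coverage (~35×). The recovery figures reported by
`scripts/acceptance.py` state what the procedure actually achieves at each
condition.

## DMR collapse and filters

Position-sorted DMSs are clustered greedily: a DMS joins the open cluster
iff its distance to the cluster's last DMS is ≤ 100 bp (a gap of exactly
100 bp joins — "within" read inclusively). The region spans first to last
DMS inclusive. Clusters with fewer than 8 (CG) / 4 (CHG) / 4 (CHH) DMSs are
discarded, as are clusters whose per-sample weighted-level spread
(max − min over samples, same context, whole region) is below 0.4 / 0.2 /
0.1. Collapse is order-independent and monotone: relaxing either filter
never removes a previously reported region.

## Interval comparisons

Merging two DMR sets produces maximal non-overlapping intervals (≥ 1 bp
overlap merges; bookended intervals do not), each labeled by contributing
source set; counts satisfy only_a + both + only_b = #merged. The overlap
permutation test re-places every interval of both sets uniformly at random
on its own chromosome each trial, preserving lengths and per-chromosome
counts; shuffled intervals may overlap each other (the simplest model
consistent with coordinate shuffling). Overlap frequency is the count of
merged intervals labeled "both" (regions, not bases), and
p = #{trials: shuffled > observed}/n_trials with a strict inequality; a
pseudo-count variant (x+1)/(n+1) bounds p away from 0. When either set is
empty no shuffle can exceed the observed overlap and the result carries a
`degenerate` flag.

Calibration of this test is checked by KS uniformity of p over 200 seeded
replicates of two independent random sets. The null design uses 200
intervals of 5 kb per set on a 10-Mb chromosome: the overlap-count null then
spans tens of attainable values, so the discrete p-grid is fine enough for a
KS test to be meaningful. With very sparse sets (e.g. 20 × 1 kb on 10 Mb)
the observed count is almost surely 0 and the strict-exceed p collapses onto
a single attainable value — a KS uniformity check is invalid by construction
in that regime, which is why the denser design was fixed a priori.

Endosperm-specific hyper-DMRs are all-context DMRs with
level(endosperm) − level(embryo) > 0.1, level(embryo) < 0.1 and
level(wild-type dry seed) < 0.1; DMRs with an undefined level in any of the
three samples are skipped. They are grouped by agglomerative clustering on
per-sample levels (Euclidean distance, complete linkage, tree cut at k = 11).
The distance/linkage pair is this package's choice — the upstream analysis
names only its plotting tool — and complete linkage was preferred for its
compact, diameter-bounded clusters on level vectors in [0,1].

Feature-overlap fractions assign each DMR to exactly one class so the
fractions sum to 1: TE when TE-overlap bp ≥ gene-overlap bp > 0 or only TEs
overlap, gene when gene bp exceeds TE bp, other when neither. The
precedence (larger overlap wins, TE on ties) is a package convention.
The replicate-consistency statistic counts DMRs whose mutant-minus-wild-type
level difference exceeds 0.2 in every replicate, excluding DMRs with
undefined levels from the denominator.

## Metaplots

Feature bodies are split into 40 equal-width bins with boundaries
`start + round(j·L/40)` (non-decreasing, tiling; bodies shorter than 40 bp
simply yield empty bins), and each 2-kb flank into 40 fixed 50-bp bins.
Per feature and bin, weighted methylation is computed from raw counts;
minus-strand features are flipped so bin 0 is always the distal upstream
end in the feature's own orientation. The profile value of a bin is the
unweighted mean over features with a defined value there (matching
"average level per bin over all features"); undefined feature-bins
contribute nothing rather than zeros. A pooled-count alternative
(coverage-weighted across features) is available by flag.

## Expression association and enrichment

Expressed genes have FPKM strictly greater than 1 in at least one sample.
Clustering runs k-means on log2(FPKM+1) rows with k = 10 and max_iter = 20,
defaulting to 10 restarts keeping the best inertia (restarts = 1 reproduces
single-run behaviour); labels are arbitrary but seed-stable. Gene–DMR
association takes candidate pairs within the gene body or 2 kb of either
gene end — both windows are 2 kb regardless of strand, so strand cannot
change the result — with distance 0 for body overlap, else the edge-to-edge
gap; only mutually closest pairs survive (each DMR its minimum-distance
gene(s), each gene its minimum-distance DMR(s)), and exact ties keep every
tied pair. Enrichment of associated genes in a cluster is
(k/n)/(K/N) with a one-sided (greater) Fisher's exact test on
[cluster vs non-cluster expressed] × [associated vs not]; this background
construction reproduces the printed worked-example p-values (1.3e-07 and
0.043) exactly, so it is the one adopted.

## The synthetic generator

`generate_methylomes` emulates the *structure* of a seed methylome
experiment: cytosines placed uniformly at per-context densities
(defaults CG 0.02, CHG 0.02, CHH 0.08 per bp — CHH most abundant, as in a
~36% GC plant genome), background true rates per context and sample
(defaults mCG 0.24, mCHG 0.07, and a germination mCHH trajectory 0.03 →
0.035 at day 0 → halving each day thereafter: a stratification gain followed
by passive dilution; a seed-development preset ramps mCHH 0.01 → 0.03
instead), TE models that override CHH rates in body and edge zones
(RdDM-like: short elements, 300–800 bp, hot 150-bp edges; CMT2-like: long
elements, 3–6 kb, hot bodies), and planted DMRs whose intervals contain
exactly n_sites near-evenly spaced cytosines (gaps ≤ 100 bp, so a fully
detected DMR collapses into one region) at specified per-sample rates.
Read depth is Poisson per site and sample (sites drawing < 5 reads exercise
the coverage filter); observed counts are Binomial(depth, p_eff) with
p_eff = p + (1−p)·r for non-conversion rate r (default 0.005), and an
unmethylated control chromosome supports the QC estimate. The expression
generator draws FPKM = 2^(archetype + N(0, σ)) − 1 floored at 0 from ten
cluster archetypes and plants DMRs within 2 kb of a configured fraction of
genes (higher in induced clusters), enabling enrichment-recovery tests.

What it does not emulate — and hence what passing tests do not show about
real data: sequence-determined cytosine spacing and strand pairing,
mappability and coverage biases, spatial autocorrelation of methylation
outside the planted structures, accession differences between genomes, and
biological replicate dispersion beyond binomial sampling.

## Problem sizes and runtime choices

The packaged checks run the caller on ~10⁴–1.5×10⁵ sites with 1000
permutations (seconds to ~1 minute), overlap calibration on 200 replicates
of 1000 trials (~15 s), and recovery on one 2-Mb chromosome — sizes at
which every statistical property being asserted is already stable.
Permutation draws are chunked (4096 sites) to bound memory. All stochastic
steps take explicit seeds (default 1); generation, calling, shuffling and
clustering are deterministic given the seed, and pipeline outputs record
the config hash and seed.

## Known limitations

- The empirical FDR is conservative in strong-signal regimes (see above);
  sensitivity at small effect sizes is bounded by per-site permutation
  resolution, not by the region filters.
- Raw-statistic cutoffs compare sites with different coverages on a common
  scale; with the per-sample ≥ 5-read filter and roughly homogeneous
  coverage this is benign, but strongly heterogeneous designs would justify
  a per-stratum threshold.
- The hierarchical-clustering distance/linkage for endosperm DMRs and the
  feature-class tie rule are package conventions, stated above.
- Accession-aware lift-over between genomes is out of scope; DMR sets being
  compared must share a coordinate system.
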