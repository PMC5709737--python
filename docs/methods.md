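# Methods

This note documents the models and procedures implemented in
`shoremap`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not demonstrate.

## Genome tiling and enrichment

The genome is partitioned into fixed-width tiles (default 1 kb);
trailing sub-width fragments are dropped so every tile has equal width,
which the downstream statistics assume. Filters remove tiles with any
blacklist overlap (≥1 bp — the conservative convention), mappability
below 0.5, and — when bisulfite data are supplied — tiles where 50% or
fewer of the CpGs reach 10× coverage. Tiles without CpGs pass the
coverage rule vacuously, since there is no methylation evidence to
demand.

Reads are assigned to tiles by their 5′ start (minus-strand reads by
`end − 1`); no fragment extension is applied. Enrichment is
`log2((IP + c)/(input + c))` after scaling both libraries to the mean
of the two library sizes, with pseudocount `c = 8`. The mean-library
normalization keeps values on a count-like scale so the pseudocount
retains its meaning; normalizing to the smaller library or to
counts-per-million are alternatives a caller can emulate by passing
explicit library sizes. The pseudocount makes the statistic finite
everywhere, shrinks low-count noise toward 0, and vanishes in influence
as counts grow.

Genome-wide track similarity is the Pearson correlation of
`log2(count + 8)` vectors over the filtered tile frame; constant tracks
have undefined correlation and are reported missing, never as 0.

## Bound-region calling

Each ChIP track is tested against input per tile under a
negative-binomial model with variance `mu + alpha*mu^2`:

1. **Size factors** are median-of-ratios: per library, the median over
   all-positive tiles of the count divided by the tile's geometric
   mean. With no all-positive tile the code falls back to total-count
   ratios, with a warning.
2. **Dispersion.** With replicated groups, a per-tile method-of-moments
   estimate from within-group residuals is shrunk toward a trend with
   10 prior degrees of freedom. Without replication (one IP vs one
   input) the only per-tile variance available is the cross-group one,
   which at genuinely bound tiles measures signal, not dispersion — so
   per-tile estimates get zero weight and every tile uses the trend.
   The trend `alpha(mu) = a0 + a1/mu` is fit on per-quantile-bin
   medians of the variance estimates; medians are insensitive to the
   small fraction of bound tiles, and each bin median is divided by the
   chi-square median factor (`chi2.ppf(0.5, dof)/dof`, ≈0.455 at 1 df)
   because the median of a few-df variance estimate is well below its
   mean. Both trend coefficients are constrained non-negative (NNLS):
   the tile means barely spread in typical data, the unconstrained
   design is near-collinear, and an unconstrained fit can extrapolate
   absurd dispersions to the high-mean tiles that matter most.
   Dispersions are clipped to [1e-8, 5].
3. **Wald test.** The statistic is the log fold change of size-factored
   group means over its delta-method standard error
   `sqrt(1/mu_ip + alpha + 1/mu_in + alpha)` (per-group means floored
   at 0.5 for stability); p-values are two-sided normal tails. On null
   simulations at depth 30 and dispersion 0.05 the realized
   fraction(p < 0.05) is ≈0.05; the normal approximation is
   conservative in the extreme tail, which the test suite documents by
   comparing the Poisson limit against the exact conditional binomial.
4. **Multiple testing.** Benjamini–Hochberg step-up, preceded by
   base-mean independent filtering: the base-mean threshold is chosen
   (over a quantile grid up to the 95th percentile) to maximize
   rejections at the target level, and only surviving tiles enter the
   adjustment. The filter statistic is independent of the test
   statistic under the null, so FDR control is preserved while the
   multiplicity burden of uninformative tiles is removed; filtered
   tiles report a missing adjusted p and are never called. Tiles with
   no read in any library are removed before testing.

Calls use fold change > 1 (natural scale) and adjusted p < 0.002. The
per-track call sets are partitioned by exact signature (every non-empty
cell of the Venn diagram over tracks), and the single-track cells are
the *exclusive* bound sets used for downstream characterization.

## Methylome segmentation

Retained CpGs (coverage strictly >10× WGBS / >20× RRBS, SNP-masked CpGs
removed; positions are the C of the CpG on the plus strand, 0-based,
strands collapsed) are smoothed with a centered 3-CpG running mean
(truncated at chromosome ends). Maximal runs of ≥4 consecutive CpGs
with smoothed fraction ≤0.5, never spanning an inter-CpG gap above
1 kb, are hypomethylated segments: UMRs at ≥30 CpGs, else LMRs. The
complementary runs of covered CpGs (equally gap-limited and broken at
hypo segments) are FMRs, so the three classes partition the retained
CpGs exactly. Segment bounds snap to the outermost member CpGs (end
exclusive at the last CpG + 1). The 0.5 cutoff, 4-CpG minimum and
30-CpG UMR/LMR split follow the established three-state framework for
mammalian methylomes; all are exposed as parameters. This is a
deterministic rule-based segmentation, not an FDR-calibrated HMM — it
is meant to be exactly testable against run enumeration, and the suite
holds it to bit-identical agreement with a brute-force oracle.

Region statistics: methylation percent is the **unweighted** mean of
per-CpG fractions (each covered CpG counts once, matching per-CpG
figure conventions; a pooled-count variant would weight deep CpGs
more), missing — not 0 — when a region has no retained CpG. Densities
are CpGs (or methylated CpGs, fraction ≥0.5) per 100 bp. FMRs are
ranked by methyl-CpG density and split into 3 equal bins (remainders
to the lowest bins, ties broken by genomic order). For meta-profiles,
UMRs/LMRs within 6 kb of another hypomethylated segment are dropped
(both members) and only FMRs ≥12 kb are kept, avoiding overlapping
windows.

UMR borders: for UMRs overlapping a gene promoter (TSS ± 1 kb; linked
by largest overlap, ties to the leftmost TSS), the borders are the end
of the nearest preceding FMR and the start of the nearest following
FMR, labelled 5′/3′ by the linked gene's strand.

## CpG islands, bivalency, shores

Islands are distance clusters: consecutive CpGs whose gap is at most
the chromosome-wide median inter-CpG gap merge; clusters with ≥10 CpGs
spanning ≥200 bp are islands. This replaces the probabilistic step of
cluster-based island callers with deterministic size filters (the
200-bp filter is applied downstream in any case); the consequence —
occasional splitting of a true island into two clusters — is visible in
the tests and harmless to classification, which matches islands by
largest overlap. Promoter-overlapping islands are linked to a gene;
mean m-CpG < 20% ⇒ unmethylated; among unmethylated islands,
overlap-weighted mean tile enrichment ≥1 (log2; i.e. ≥2-fold) for
*both* H3K4me3 and H3K27me3 ⇒ bivalent, H3K4me3 alone ⇒
H3K27me3-negative, anything else unclassified. The 2-fold cutoff is a
configurable default; published bivalency thresholds vary and no
universal value exists. Shores are `[start − w, start)` and
`[end, end + w)` with `w = 2 kb`, clipped at chromosome bounds and
labelled 5′/3′ by gene strand.

## Profiles, clustering, dynamics, class enrichment

Profile rows allocate per-tile counts into bins by fractional overlap,
i.e. reads are treated as uniform within a tile; this is exact for the
tile-level simulation and a ≤1-tile-width smoothing for real data.
Rows are strand-flipped so column 0 is 5′, normalized to reads per bin
per 10⁷ library reads (scaling every count by a constant therefore
leaves profiles unchanged), and NaN-padded where a window leaves the
chromosome (such bins are excluded from column means). Meta-gene
profiles use fixed flanks plus a gene body rescaled to a fixed bin
count in density units, so a spatially constant track is flat across
the flank/body boundary; overlapping genes and genes shorter than the
bin count are dropped.

UMR clustering is k-means (k-means++, 10 restarts, fixed seed,
recorded) on `log2(signal + 8)` rows — the same transform as the
global enrichment scale. Binding dynamics between conditions are
pseudocounted log2 fold changes per tile after mean-library scaling
(identical libraries give exactly 0; swapping conditions flips the
sign), optionally restricted to tiles positive for a mark in either
condition. Ranked-window medians sort tiles by a key (e.g. methylation
gain), cut consecutive blocks of 500, and keep a trailing block only
if it holds at least half a block (otherwise it merges into the
previous one — a short tail would contribute a high-variance point).
Promoter-class enrichment of an externally supplied deregulated-gene
list is the upper-tail hypergeometric probability per class, reported
significant at p < 0.05; differential expression itself is out of
scope.

## Synthetic data: what it emulates, and what it does not

The generator plants, on a configurable number of chromosomes
(default 2 × 5 Mb):

- non-overlapping CpG islands (default 20 × 2 kb, half bivalent),
  placed uniformly with separation > 2 shore widths, each with a gene
  whose TSS sits at the island midpoint; genes at bivalent islands are
  transcriptionally silent (Polycomb-repressed), genes at active
  islands are transcribed with probability 0.5, plus distal genes;
- a methylome with unmethylated island interiors (true fraction 0.05),
  methylated shores (0.85), planted distal LMRs (0.25) and a
  fully-methylated background (0.80); CpG spacing is geometric with
  mean 12 bp inside islands, 30 bp in LMRs and 100 bp elsewhere,
  giving the ~8× density contrast of real islands;
- per-tile ChIP counts drawn from a gamma-Poisson (negative binomial)
  with mean = depth × planted fold and dispersion 0.05 (Poisson in the
  zero-dispersion limit). Default folds: DNMT3A1 8× at bivalent shores
  and borders; DNMT3B 8× and H3K36me3 6× in transcribed bodies;
  H3K4me3 6× at island centers; H3K27me3 6×/4×/2× at bivalent
  centers/borders/shores; 5-hmC 6× at bivalent island borders
  (edge ± 500 bp); DNMT3A2 and input flat — the isoform contrast the
  analysis must recover. Depth 30 reads/tile and dispersion 0.05 are
  calibration choices for a desk-scale study; the counts of a real
  experiment depend on sequencing depth and are exposed in the config;
- bisulfite calls with Poisson coverage (mean 30×) and binomial
  methylated counts; an optional expander turns tile counts into
  uniform read starts to exercise the counting path.

Each tile takes the class with the largest overlap (ties by a fixed
priority), and per-track "expected bound" truth tiles are those whose
class carries a planted fold ≥2. One global seed fans out into named
substreams (truth, per-track counts, bisulfite, expansion), so adding
a track never perturbs existing draws and every fixture is
bit-reproducible.

What passing the recovery tests shows: the pipeline detects the planted
shore-specific binding (sensitivity ≥0.9, precision ≥0.95 at the
default conditions), reproduces the segmentation boundaries to within
2 CpGs, classifies bivalency correctly, and localizes the 5-hmC border
signal to within one 500-bp bin of a planted border. What it does not
show: robustness to GC/mappability bias, fragment-length effects,
copy-number structure, bisulfite conversion errors, non-CpG
methylation, or realistic island size/spacing distributions — none of
which the generator emulates. Note also that the synthetic islands are
only 2 kb wide, so a border-anchored profile sees the island's opposite
border ~2 kb away on the unmethylated side; peak localization is
therefore assessed against the nearest planted border.

## Problem sizes and numerical choices

The default study is 10,000 tiles, ~100k CpGs, 20 islands and 40 UMR
borders — large enough for the caller's asymptotics (the null
calibration check uses the full 10,000 tiles) while keeping a full
pipeline run around a second. Determinism is absolute: artifact files
carry no timestamps and reruns are bit-identical. Degenerate inputs are
handled explicitly: empty BH input returns empty; chromosomes with
fewer CpGs than the smoothing window are skipped with a warning;
regions without CpGs report missing statistics; islands without
overlapping filtered tiles stay unclassified; UMRs lacking a flanking
FMR lose that border, logged.

## Known limitations

- The NB Wald p-value is conservative in the far tail relative to
  exact conditional tests; calls at p ≈ 0.002 are unaffected.
- The caller re-implements the *minimal* equivalent of the established
  count-based framework (no Cox–Reid adjustment, no MAP dispersion
  outlier handling, no LFC shrinkage); exact region counts from any
  specific external implementation are not reproduced.
- The island caller's median-gap rule can split a true island when an
  interior gap exceeds the genome-median; classification matches by
  overlap and is insensitive to this, but island counts are not a
  stable statistic of this method.
- `filter_segments_for_profiles` and gene-overlap detection are
  quadratic per chromosome in segment/gene count — fine at desk scale,
  replaceable by interval trees for genome-scale annotation sets.
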