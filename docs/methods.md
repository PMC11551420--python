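# Methods

## Coordinates and file handling

All in-memory coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read and write, BED/narrowPeak are native. TSS and TTS
are strand-aware: a minus-strand gene's TSS is the last base of its
interval, and every "distance to TSS" in the package is the signed
strand-aware offset (negative = upstream of the gene). Multi-transcript
genes collapse to their longest mRNA — a convention, chosen because the
analysis is gene-level throughout. narrowPeak summits with offset −1
fall back to the interval midpoint (floor). Sequence fetches never clip:
out-of-bounds requests raise, so silent truncation cannot corrupt
binding-site windows.

## Binding and direct-target inference

A replicate-A peak is *reproducible* when it overlaps any replicate-B
peak by ≥ 1 bp; the A coordinates and summit are retained. This is the
simplest deterministic reconciliation rule and is exactly testable on
synthetic replicates (an IDR-style analysis is out of scope). Binding is
decided by the *summit*, not interval overlap: a gene is bound when a
summit lies in [TSS − 1000, TTS] in strand-aware coordinates. One peak
may bind several genes (no nearest-gene collapse) because target
counting is per-gene; only the genomic-feature annotation, which needs
one category per peak, breaks ties — precedence 5′ UTR > exon > intron >
3′ UTR > 2 kb upstream > 1 kb downstream > intergenic, then nearest TSS.
Gene-internal categories outrank flanking ones deliberately: the
binding mode under study is intragenic.

Coexpression: a gene passes a contrast when log2FC ≥ log2(2) and BH
FDR < 0.01, and is called coexpressed when it passes ≥ 2 of the four
embryo-vs-seed-coat contrasts. Both thresholds and the contrast pairing
are parameters (`min_fold`, `fdr_max`, `min_contrasts`); the defaults
are the analysis's reference values (a looser FDR < 0.05 default applies
to ordinary two-condition DE, surfaced as `de_fdr`). DT genes are the
exact set intersection — no scoring, no ranking.

## Differential expression engine

The engine is intentionally compact rather than a port of a full
quantile-adjusted CML estimator with tagwise shrinkage:

1. **TMM effective size factors.** M- and A-values are computed on raw
   counts against a reference sample (upper quartile closest to the mean
   upper quartile); genes zero in either sample are dropped; M is doubly
   trimmed (30% on M, 5% on A); the factor is 2^(precision-weighted mean
   M) with delta-method weights 1/(1/y_j + 1/y_r), normalized to
   geometric mean 1. Note the factors here *absorb sequencing depth*
   (they are effective size factors, not composition-only factors):
   scaling one sample's counts by c scales its factor by c, and dividing
   counts by the factor puts all samples on one scale. This is the
   convention the rest of the package relies on.
2. **Common dispersion** by method of moments: pooled
   Σ(s² − m̄)/Σm̄² across genes with within-group mean > 1, floored at
   1e−6. With thousands of genes the pooled ratio estimator is accurate
   enough for calibrated testing (measured type-I error 0.046–0.053 at
   α = 0.05 in the validation suite).
3. **Conditional NB exact test.** Group sums of n i.i.d. NB(μ, φ)
   counts are NB(nμ, φ/n). Conditional on the total t, P(Y_A = y | t) is
   the normalized product of the two NB pmfs (the NB success probability
   cancels); the two-sided p sums all conditional outcomes no more
   probable than the observed one, with 1e−8 relative slack for float
   ties. As φ → 0 this reduces to binomial conditioning (the Poisson
   limit), which the tests verify to 1e−6. log2FC uses normalized group
   means with a 0.5 pseudo-count; all-zero genes get p = 1, log2FC = 0.

Externally computed DE tables (gene, log2fc, pvalue, fdr) can be
injected into the pipeline in place of the built-in engine.

## Motif scanning and the two nulls

IUPAC scanning is table-driven and double-stranded by default (a region
is motif-positive if the consensus matches the forward sequence or its
reverse complement; single-strand scanning is a flag). An `N` in the
*sequence* is matched only by the motif code `N` — ambiguous bases never
satisfy a specific consensus position. Matches of the reverse-complement
pattern are reported at their forward-strand offset with strand `-`;
palindromic consensi therefore report both strands at one offset, which
keeps the match count invariant under reverse complementation.

**Matched random regions.** "Equivalently sized and spaced" is
interpreted as: for each binding site, one region of identical width
placed at the site's strand-aware TSS offset on a uniformly drawn random
gene, rejection-resampled (≤ 1000 attempts) when out of bounds. This
controls for both length and the downstream positional bias that would
otherwise confound GC-sensitive motifs. Enrichment is a one-sided Fisher
exact test (enriched direction only) with Bonferroni correction over the
motifs in the call (m = 5 for the standard panel), significance at
adjusted p < 0.01.

**Gene-set null.** Motif presence is precomputed once per gene for the
500 bp window on the chosen side of the TSS; each of the 1,000 background
sets is a uniform sample of genes without replacement (no GC or length
matching — a documented convention, since no matching covariates are
defined), and the empirical p is (1 + #{background ≥ observed}) /
(n_sets + 1), floored at 1/1001.

## QC metrics

NRF is distinct (chrom, pos, strand) tag triples over total tags. Strand
cross-correlation is the Pearson correlation of plus- and minus-strand
tag-start vectors at each shift; the fragment-length estimate is the
argmax excluding ± 5 bp around the read length (the phantom peak).
Zero-variance vectors report correlation 0 with a warning flag rather
than NaN.

## Synthetic study conditions

The generator emulates the statistical structure of the real study, not
its sequence content:

- **Genome**: i.i.d. bases at GC 0.38 (a plant-genome-like value);
  non-overlapping genes with alternating strands, 1.5–4 kb long, 1–3
  exons with terminal UTRs, separated by ≥ 2.5 kb so no gene's upstream
  window reaches a neighbour (this is what makes exact bound-set
  recovery well-defined).
- **Peaks**: one peak per selected gene, summit offset drawn from a
  mixture that is 80% Normal(+300, 150) downstream and 20%
  Uniform(−1000, −1) upstream, clipped into the gene's bound window —
  reproducing predominantly downstream binding. Replicate B jitters
  boundaries by ≤ 10 bp; both replicates receive replicate-unique
  intergenic noise peaks at the configured fraction.
- **Motifs**: a fraction of sites (default 0.56, the reference
  binding-site fraction for the strongest gene class) receives a
  concrete motif instance — degenerate positions resolved uniformly, so
  the chance rate stays analytically computable — written into the
  genome under the summit.
- **Counts**: NB with gene means log-uniform in [50, 500], dispersion
  0.1, and a planted fold change (default 4) applied to a random 30% of
  genes in the two embryo-like groups; 3 replicates per group by
  default.
- **Second TF**: summits at signed-exponential offsets with median
  |offset| 142 bp from TF-A summits (the reference co-localization
  scale).

One global seed drives all stages via `default_rng([seed, stage_index])`
so datasets are bit-reproducible and stages independently perturbable.

What the generator does *not* emulate: real base composition and
repeats, isoform structure, peak-width and score variation, count
outliers/batch effects, and any biological correlation between binding
and expression beyond the planted sets. Passing tests therefore
demonstrate algorithmic correctness under controlled conditions, not
performance on real libraries.

### Problem sizes in the validation suite

The planted-truth run uses 2,000 genes / 500 peaks on a 12 × 1.2 Mb
genome. *Exact* recovery of the coexpressed set is only meaningful where
threshold calls are deterministic, so that run uses a strong-signal
regime chosen a priori: fold 8, dispersion 0.05, means in [200, 1000],
4 replicates per group — planted genes then pass all four contrasts with
probability ≈ 1 and null genes essentially never pass two. Calibration
checks (type-I error, power) use the reference NB conditions (mean 100,
dispersion 0.1, 3 vs 3, 4-fold). Enrichment power/type-I use 100 seeded
datasets of 200 sites each; the gene-set null uses 300 target genes of
1,000 with 70% vs 40% planting, where the planted gap is ≈ 5 sd of the
background fraction and the empirical p floors at 1/1001.

## Numerical choices and edge cases

- Hypergeometric tails and Fisher exact tests come from scipy (log-space
  internally); BH from statsmodels; both are re-verified against
  exhaustive enumeration in the tests.
- Wilcoxon rank-sum switches from exact enumeration to the tie- and
  continuity-corrected normal approximation at min sample size > 8 or
  any tie — a fixed, documented boundary.
- Fragment-length argmax ties break toward the smaller shift;
  feature-annotation ties break by rank then nearest TSS; TMM trimming
  that removes everything falls back to the untrimmed mean (degenerate
  two-gene inputs).
- Empty inputs raise early (NRF of zero tags, enrichment with empty
  region lists, Wilcoxon with an empty sample) rather than propagating
  NaNs.

## Known limitations

No peak calling, IDR, read-level simulation, PWM scoring, de novo motif
discovery, or GO-DAG propagation (term→gene maps are consumed flat). The
DE engine assumes a common dispersion; strongly gene-specific dispersion
inflates its error rates. Matched-background sampling assumes the
annotation provides enough genes that random placement is representative;
with very few genes the background degenerates toward the sites
themselves.
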