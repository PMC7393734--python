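# Methods

## Statistical model

A feature (a gene's merged coding intervals, or a BED region) of testable
length *L* nucleotides is tested against a per-nucleotide, per-sample
background somatic mutation probability *p*. Assuming independent,
position-homogeneous mutation within the feature, a sample carries ≥ 1
mutation with probability *pₙ* = 1 − (1 − *p*)^*L*, evaluated as
`-expm1(L * log1p(-p))` so that rates of 1e-6/nt over megabase lengths do not
lose precision.

Two test families are implemented:

* **Binomial (default).** The number of mutated samples *n* out of *N* is
  referred to the upper tail of Bin(*N*, *pₙ*). It counts *samples*, so one
  hypermutated tumor cannot drive a call.
* **Negative binomial.** The total mutation count *k* is referred to the
  negative-binomial tail over *x* = *L·N* nucleotide trials,
  Σᵣ₌₀^(x−k) C(k+r−1, r) p^k (1−p)^r, computed as `nbinom.cdf(x−k, k, p)`
  (identically the upper binomial tail P(Bin(x, p) ≥ k), an identity the test
  suite asserts to 1e-10 against naive summation). It counts *mutations*, so
  recurrent multi-hit genes in few samples become visible.

Observing nothing is never evidence: *n* = 0 (or *k* = 0) returns exactly 1.

In the coding module the foreground is non-silent mutations (the spectrum of
ANNOVAR-style exonic terms: nonsynonymous SNV, stopgain/stoploss/startloss,
frameshift and non-frameshift indels, splicing); in the noncoding module the
foreground is every somatic mutation in the region. Both tails are evaluated
through scipy survival functions; exhaustive-summation oracles live only in
the tests.

## Background mutation rates

Four per-sample estimators, selected by `--bg-method`:

* **global** — the sample's mutation count summed over all features divided
  by the total feature length; one rate per sample.
* **local** — windows of `--window-size` (default 1 Mb, accepted range
  1–2 Mb) are slid across each feature from "feature at the right edge" to
  "feature at the left edge" in steps of a quarter window, clipped at
  chromosome bounds; the rate is the *maximal* windowed density. The maximum
  is deliberately conservative for features inside locally hypermutated
  neighborhoods. Features longer than the window fall back to a single
  feature-spanning window, with a warning. The step size is a cost/fidelity
  compromise; placements are enumerated identically by the test oracle.
* **clustered** — features are z-scored on user covariates (GC fraction,
  replication timing, ... ; `prepare_covariates` builds the table from a
  FASTA and BED4 score tracks) and grouped by affinity propagation
  (negative squared Euclidean similarity, median preference, damping 0.9,
  ≤ 1000 iterations, features sorted by id first so the partition is
  input-order invariant). A sample's rate for a feature is the pooled density
  over the feature's cluster. Non-convergence falls back to a single
  all-features cluster, flagged `ap_fallback` — which makes the method
  degrade exactly to `global`.
* **local_clustered** — per cluster member the local windowed maximum is
  computed; the feature's rate is the length-weighted mean over members
  (a max-of-max across a cluster would be pathologically conservative).

The per-feature aggregate *p* is the geometric mean of sample-wise rates over
**foreground samples**: samples with at least one foreground mutation
anywhere in the analyzed feature set. Restricting to mutated samples follows
the view that unmutated (or shallowly sequenced) samples carry no rate
information, at the cost of an upward conditioning bias when per-sample
mutation counts are small (see *Limitations*). Rates are floored at 1e-8/nt
(≈ one mutation per 100 Mb) before the log so a single zero cannot
annihilate the mean. If no sample carries any foreground mutation the whole
run is untestable: burden p-values are reported as 1 and flagged.

By default all mutation classes inside features count toward the background
(`--bg-count-class all`), so in the coding module silent and unannotated
genic mutations inform the rate while only non-silent ones are tested;
`--bg-count-class foreground` restricts the background to the tested class.

## Hotspots, WAP, combination, FDR

Sorted foreground positions are chained while consecutive gaps are ≤
`--max-gap` (50 nt, inclusive). Groups with ≥ `--min-hs-muts` (5) mutations
from ≥ `--min-hs-samples` (3) distinct samples become hotspots, spanning
min to max mutated position, and are tested on their own span with the
feature's aggregate rate under the selected test family.

The WAP statistic (noncoding module, regions with ≥ 2 mutations) is the mean
over unordered position pairs of exp(−d²/(2s²)) with Gaussian scale
`--wap-scale` s = 30 nt — 1.0 iff all positions coincide, translation
invariant. Significance comes from `--n-permutations` (10,000) redraws of the
same number of positions, independently uniform within the region's
intervals, with the add-one estimate (1 + #{WAP* ≥ WAP}) / (1 + n_perm). The
kernel form and scale are configuration choices, not estimates; the null
ignores sequence context by design.

Per feature, Fisher's method (−2 Σ ln pᵢ on χ² with 2m df) combines the
burden p-value with the best (minimum) hotspot p-value when a hotspot exists;
features without hotspots keep combined = burden. WAP joins the combination
only under `--combine-wap`, since it is conceptually a second clustering test
of the same signal as the hotspot scan. Components below 1e-300 are clamped
there before the log. Benjamini–Hochberg q-values are computed in separate
families: burden over features, combined over features, hotspot p-values over
the hotspot table, and WAP over WAP-tested features.

## Determinism and parallelism

Feature-level computations are independent and are partitioned across
`--processors` worker processes. Permutation seeds are derived per feature as
`(master_seed * 1000003 + crc32(feature_id)) mod (2³¹ − 1)`, so results are
bit-identical for any worker count; output rows are sorted (combined q,
combined p, feature id — and p, id, position for hotspots) and floats
printed at six significant digits, making whole files byte-reproducible.

## Synthetic data generator

`mutburden.simulate` emulates the study conditions the statistical machinery
assumes: per sample and feature, Poisson(rate × multiplier × L) mutations
placed uniformly within the feature's intervals; optional planted hotspots
add exactly one mutation per randomly chosen carrier inside a short window;
genic mutations are labelled silent with a configurable probability
(0.3 in the coding fixtures, roughly the synonymous fraction of exonic SNVs);
SNVs only, one alternate allele, reference alleles read from the generated
random genome. Defaults are a 100-sample cohort at 1e-6 mutations/nt/sample
(one per megabase, a typical tumor WGS load) over 2 kb features. Toy
annotations tile three-exon genes (exons double as CDS) with promoters in the
two standard definitions, 100 nt and 2000 nt upstream of the TSS
(strand-aware).

What the generator deliberately omits: mutational signatures and
sequence-context bias, regional covariate structure (replication timing, GC
effects), copy-number and structural variation, indels (behind a flag), and
sample-level hypermutators beyond Poisson spread. Passing tests therefore
demonstrate correctness of the estimators and tests under their own
assumptions — calibration on homogeneous backgrounds, recovery of planted
signals — not robustness to the covariate-driven rate heterogeneity of real
genomes, which is exactly what the local and clustered background methods
exist to absorb.

## Numerical and policy choices

* Internal coordinates are 0-based half-open everywhere; GTF/VCF/MAF are
  converted on input and all reports print 1-based inclusive.
* Variants identical in (sample, chrom, pos, ref, alt) are deduplicated;
  multi-allelic VCF rows split per alternate allele; indels are assigned to
  the feature containing their start position.
* Genes are built from CDS rows when present, else exons, merged across
  transcripts; genes spanning multiple chromosomes are dropped with a
  warning. Strand is carried but never used in statistics.
* Overlapping BED regions are analyzed independently; duplicate identical
  lines are dropped; repeated names get `#2`, `#3`... suffixes.
* Tie-breaks are lexicographic on feature id (result ordering) and leftmost
  position (best hotspot among equal p-values).
* A MAF cannot name unmutated samples, so MAF cohorts take N from distinct
  tumor barcodes; supplying VCFs (one per sample, empty allowed) is the
  accurate route when truly mutation-free samples exist.

## Problem sizes used in the checks

The acceptance computations run 100-sample cohorts over 500 (calibration,
power) or 201 (hotspot rescue) 2 kb regions on a 2.2 Mb toy chromosome, ten
seeds for calibration, 10,000 WAP permutations for the coincident-position
check and 999 per replicate for the 200-replicate uniformity check — sizes
chosen so the whole script reruns from scratch in seconds while keeping ≥ 4σ
separation on every planted effect.

## Limitations

* The geometric-mean aggregation over mutated samples is upward-biased when
  expected per-sample mutation counts are near 1 (conditioning on ≥ 1
  mutation): at 1e-6/nt over 1 Mb of features the estimate concentrates
  ~40% above the generating rate. The bias shrinks as total feature length
  or mutation load grows (real WGS cohorts have thousands of mutations per
  sample) and is conservative in direction, but parameter-recovery checks at
  sparse toy scales show it plainly.
* Burden power at small effect sizes is bounded by counting statistics: a
  10× rate increase over 2 kb at 1e-6/nt yields ~2 expected mutated samples
  per 100 — indistinguishable after FDR over hundreds of features under any
  test of these counts. Detecting such features requires positional
  concentration (hotspot, WAP), longer features, or larger cohorts.
* Hotspot spans may bridge intron gaps inside multi-interval genes when
  mutations in adjacent exons fall within `--max-gap` (distance is genomic).
* p-values are exact tails of the assumed null, not permutation-calibrated;
  discreteness makes them conservative at small *n*.
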