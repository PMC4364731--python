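# Methods

## Scope and model

`cisprior` is a deterministic annotation pipeline, not a statistical model
with free parameters: given a lead-SNP table, a pairwise LD table, a
per-variant annotation table, selection statistics, a variant-to-gene map
and disease gene sets, it computes locus expansions, constraint classes,
cutoff concordance, fold enrichments and cross-disease LD overlaps. Every
threshold is explicit configuration (`PipelineConfig`); nothing is learned
from the data. The only stochastic component is the synthetic-data
generator.

The pipeline assumes its inputs were produced upstream: r² values come from
a reference-panel LD calculation, annotation scores from the respective
scoring tools, and selection statistics from alignment- and
population-based pipelines. None of these are recomputed here — scores are
taken as given, which is also why all comparisons are specified inclusively
on the printed threshold values rather than re-derived.

## Thresholds and their meaning

| parameter         | default | meaning                                                        |
|-------------------|---------|----------------------------------------------------------------|
| `r2_min`          | 0.8     | minimum r² for a proxy to join a lead's locus (inclusive)      |
| `cadd_cut`        | 10      | deleteriousness cutoff; ≥10 ≈ top 10% of possible substitutions |
| `gwava_cut`       | 0.4     | functional-impact cutoff on the [0,1] score (inclusive)        |
| `regdb_cut_major` | 2       | regulatory category passes iff major category ≤ 2              |
| `rs_strong`       | 2       | RS ≥ 2 marks strong negative selection                         |
| `td_strong`       | 2       | Tajima's D > 2 marks balancing selection                       |
| `daf_high`        | 0.8     | DAF ≥ 0.8 marks near-fixed derived alleles                     |
| `background_N`    | 30,000  | genome gene background for fold enrichment                     |

Two deliberate asymmetries: the RS-only strong-constraint class is
inclusive (RS ≥ 2) while the joint RS-and-TD class is strict on both
(RS > 2 and TD > 2), mirroring how the two classes are conventionally
quoted; and summary descriptions of score distributions that use "greater
than" phrasing are treated as strict while the concordance cutoffs are
inclusive. Both are configurable rather than hard-coded.

The regulatory category is an ordinal scale 1a < 1b < … < 2c < 3a < 3b <
4 < 5 < 6 (14 informative tokens); major category 7 (aliases `ND`, `.`)
means "no annotation data" and fails the category cutoff — variants with
no data are retained in the universe with failing flags, never dropped,
so denominators always refer to the full universe.

## Statistical kernels

*Rank-sum test.* Mid-ranks for ties. For two tie-free samples of at most 8
observations each, the null distribution of the rank-sum is enumerated over
all C(n+m, n) rank assignments and the two-sided p-value is
2·min(P(W≤w), P(W≥w)) capped at 1. Larger or tied samples use the normal
approximation with tie-corrected variance
n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction —
matching the asymptotic two-sided behaviour of the standard R
implementation, which is the convention downstream numbers are quoted in.
Two identical samples yield p = 1 with a warning rather than an error.

*Hypergeometric / Fisher.* The pmf is evaluated via log-gamma
accumulation, exact in practice to ~1e-15 at N = 30,000 (naive factorials
overflow long before that). The two-sided Fisher p-value uses the
minimum-likelihood convention: sum pmf(k) over all k in the support with
pmf(k) ≤ pmf(m)·(1+1e-7); the relative slack reproduces the tie behaviour
of the reference R implementation. One-sided use is possible by summing
tails of the pmf directly.

*Fold enrichment.* E = (m/n)/(M/N), with m = 0 giving 0 and n = 0 or
M = 0 reported as undefined rather than silently dropped. Gene counting is
over distinct symbols: a symbol adjacent to several prioritized variants
counts once, which keeps n consistent between the prioritized table and
the enrichment sweep. Pooled multi-disease reference sets are plain set
unions. Significance is annotated at p ≤ 0.01 with no multiple-testing
correction, matching how such enrichment tables are conventionally read;
the p-values are descriptive, not inferential.

## Duplicate and missing-data policy

An rsID can appear on several annotation rows (one deleteriousness score
per substitution at multi-allelic sites). Duplicates collapse
risk-maximally: maximum deleteriousness score, maximum non-missing
functional score, best-ranked non-missing regulatory category. Missing
values (`NA`, `.`, empty) are equivalent; a missing score fails only its
own cutoff. Positions are 1-based throughout; BED export converts to
0-based half-open at the boundary. Strand is ignored. Gene cells of `-`
parse to an empty list.

A proxy in strong LD with two leads belongs to both loci (needed for
distinct-locus counting) but appears once in the universe; a lead that is
its own proxy stays a single lead-role record. In cross-disease overlap, a
prioritized SNP that is itself a lead SNP of the reference disease counts
as a self-match with r² = 1.

## Synthetic cohorts

`generate_cohort` emulates the structure of a real post-GWAS retrieval:

- 152 loci with Poisson(30) candidate proxies each, r² ~ Uniform(0.5, 1)
  (so the LD filter at 0.8 is actually exercised); proxies are ~94% SNPs,
  ~4.4% deletions, ~1.6% insertions; indels carry no functional score.
- A single latent functional indicator (default fraction 0.03) drives all
  three annotators — the minimal dependence structure under which triple
  concordance is informative. Background scores: Gamma(1.2, 2.9)
  deleteriousness (mean ≈ 3.5, matching the empirical distribution of such
  scores over LD variants), Beta(1.5, 6) functional score (mean ≈ 0.2),
  and a categorical regulatory table with a 41% no-data mass. Functional
  variants draw from a location-shifted Gamma (8 + Gamma(2, 3)),
  Beta(6, 2), and a category table concentrated in categories 1–2.
- Selection statistics for leads: NR ~ Uniform(1, 6); RS = NR with
  probability 0.125 (no observed substitution), otherwise Normal(0.2, 1.5)
  truncated at NR; TD ~ Normal(1.8, 1.2) clipped to [−2.5, 4];
  DAF ~ Beta(2, 2) with ΔDAF derived as a DAF difference; ~2.6% of leads
  lack population statistics, exercising the missing-data denominators.
- Gene map: up to 4 symbols per locus (`SYNG…` namespace; rsIDs use
  `rsS…` to avoid collisions with real identifiers), each kept per variant
  with probability 0.7.
- The planted disease set is constructed against the genes of the variants
  that actually pass all three cutoffs in the strong-LD universe:
  m\* = round(E\*·n·M/N) of them enter the set, padded with filler symbols
  disjoint from the cohort. Evaluated fold therefore recovers E\* up to
  rounding of m\*; recovery tests choose M ≈ N/(2E\*) so the planted
  overlap sits near n/2 and rounding error stays ≪ the ±20% criterion.
  An infeasible request (m\* > min(n, M)) raises before any file is
  written; a cohort with no concordant variants gets a pure-filler set.

All randomness flows through a single `numpy` generator seeded from the
spec; equal seeds give byte-identical files.

What the generator does **not** emulate: genotype-level LD (r² is drawn,
not computed), within-locus score correlation beyond the shared indicator,
realistic allele-frequency spectra, chromosome-level clustering of loci,
and annotation-tool score calibration. Tests passing on synthetic cohorts
therefore demonstrate the pipeline's bookkeeping and statistical kernels,
not the biological validity of any particular cutoff.

## Problem sizes

The default synthetic cohort (152 loci, ~4,600 candidate proxies, ~2,000
strong-LD variants) matches the scale of the study conditions the package
targets; recovery tests run 30 seeds per planted fold and the null-cohort
concordance test pools 30 smaller cohorts (60 loci) against a closed-form
Poisson expectation computed from the background tail masses.

## Known limitations

- The bundled reference tables cover the published prioritized set and its
  cross-disease overlap; the full per-variant score tables of the original
  cohort are article supplements and are not redistributed, so the
  full-cohort counts (Venn union 929, per-tool 323/509/297, selection
  16/77/94) can only be re-checked after supplying those tables in the
  documented schema.
- Fisher p-values at very extreme enrichment (p < 1e-250) underflow to 0;
  the fold estimate itself is unaffected.
- The exact rank-sum path is enumerative and limited to samples of ≤ 8 by
  default; the asymptotic path is the operative one at realistic sizes.
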