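# Methods

## Model and procedure

`sweepscan` detects candidate selective sweeps from the joint signature of
between-population differentiation and within-population diversity loss.

**Per-SNP statistics.** For each biallelic SNP, alt-allele frequencies are
computed per population from non-missing alleles (`n_k` = 2 × called
samples).  Expected heterozygosity is `He = 2p(1-p)`.  The default FST is
the Wright/Nei-style ratio `FST = (HT - HS)/HT`, with `HT = 2 p̄ (1-p̄)`
from the pooled frequency `p̄ = Σ n_k p_k / Σ n_k` and
`HS = Σ n_k He_k / Σ n_k`.  Weighting by non-missing allele counts is a
deliberate choice: "weighted average" admits several readings, and
allele-count weights handle missingness and unequal sample sizes in one
rule while guaranteeing `HS ≤ HT` (Jensen's inequality on the concave map
`p ↦ 2p(1-p)`), hence `FST ∈ [0, 1]` wherever defined.  Globally
monomorphic sites (`HT = 0`) leave FST undefined rather than zero — the
ratio has no value there — and are excluded from window FST aggregation
while still contributing to window He.  No small-sample (`2n/(2n-1)`)
correction is applied in this mode.  A vectorized Weir & Cockerham (1984)
θ (`mode="wc"`), which does correct for sample size and uses observed
heterozygote counts, is provided for comparison; it is validated by
invariance tests (population-label exchange, allele relabelling, fixed
differences → θ = 1) and by its high rank agreement with the default
estimator on simulated data, but has no independent reference
implementation in the test suite.

**Windows.** Chromosomes are tiled with 100-kb windows advanced by 50 kb,
anchored at position 1.  The last window on a chromosome is the first one
running past the chromosome end and is truncated there, so a chromosome
shorter than one window yields exactly one window.  Window H is the
arithmetic mean of the focal population's per-SNP He; window FST defaults
to the ratio of sums `Σ(HT-HS)/ΣHT`, which weights SNPs by their
informativeness and is robust to low-He sites (a per-SNP-mean mode
exists).  Windows with fewer than `min_snps = 10` SNPs carry no statistics
and do not enter the quantile computation — without this floor,
near-empty windows with noisy single-SNP values dominate both tails.

**Thresholds and regions.** The FST threshold is the 95th percentile
(linear interpolation between order statistics) of eligible window FST;
the H threshold is the 5th percentile of window H, i.e. the scan treats
the *low* tail of heterozygosity as the selection signal.  Selection uses
strict inequalities (`FST > thr`, `H < thr`), so exactly tied values are
excluded and a degenerate all-equal distribution selects nothing.  A
window is a candidate only when it passes *both* thresholds (the
intersection criterion — this is what pushes specificity well past either
single 5% cut); overlapping or book-ended candidate windows merge into
regions annotated with their member count, max FST and min H.  The
intersection is taken at window level before merging, and window H is the
focal population's (both points are ambiguous in principle; the
window-level AND is the stricter reading, and a single shared H threshold
across comparisons is only meaningful if H is the focal population's).

**Genes and set algebra.** Regions map to genes by ≥1 bp interval overlap
(configurable), 1-based inclusive coordinates on both sides; BED input and
output are converted at the file boundary only.  Across comparisons, the
deduplicated union (first-seen order) gives the overall candidate set; the
intersection across all comparisons gives the genes selected against every
reference — for two comparisons these satisfy
`|A| + |B| = |A ∪ B| + |A ∩ B|`, which the tests exercise.

**Enrichment.** One-sided hypergeometric over-representation per term,
background defaulting to the full annotation.  The correction is
`FDR_i = p_i · n / rank_i` with ascending 1-based ranks — the
Benjamini–Hochberg quantity *without* the step-up monotonicity pass — as
the default, with `mode="monotone"` applying the cumulative-minimum pass
(then it equals statsmodels' `fdr_bh`, which the tests verify).  Ties in p
take ordinal ranks, deterministic through a pre-sort by (p, term id); a
max-rank tie mode mirrors common BH code.  Values are capped at 1.

**Structure.** Pairwise distance is allele-sharing identity-by-state,
`d(a,b) = mean |dos_a - dos_b| / 2` over jointly called SNPs — the
conventional SNP distance; substitution models for protein or nucleotide
alignments do not apply to dosage data.  Trees come from a from-scratch
Saitou–Nei neighbor-joining implementation (Q-criterion pair choice,
standard limb-length formulas, negative limbs clamped to zero with the
deficit moved to the sister limb so the pair's span is preserved);
scikit-bio supplies only the containers and newick serialization, and its
own NJ serves as an independent cross-check in the tests.  Bootstrap
support resamples SNP columns with replacement (default 100 replicates at
desk scale) and reports the percentage of replicate trees containing each
internal bipartition.  PCA mean-imputes missing dosages, centres each SNP
and by default applies Patterson normalization (dividing by
`sqrt(p̄(1-p̄))`), then takes the SVD of the sample × SNP matrix;
requesting more components than the data rank reduces `k` with a warning.

## The simulator

The generator draws, per SNP, an ancestral frequency `p ~ U(0.05, 0.95)`
and per-population frequencies from the Balding–Nichols construction
`Beta(p(1-F)/F, (1-p)(1-F)/F)`, so `F` sets the expected differentiation.
Inside a planted sweep the focal population draws with `F = sweep_F` and
the result is mixed toward the nearer frequency boundary with weight
`fixation_bias`, jointly producing elevated FST and depressed He — the
exact signature the scan thresholds on.  Genotypes are independent
binomial(2, freq) draws; missingness, when requested, is uniform.

Default condition: 2 populations × 30 diploids, 2 chromosomes × 5 Mb,
10,000 SNPs (≈100 per window), background `F = 0.05`, one 300-kb sweep
with `sweep_F = 0.6` and `fixation_bias = 0.7`, no missing data.  These
sizes run the full pipeline in seconds while leaving ~100 SNPs per window,
enough for stable window statistics.  `missing_rate` defaults to 0 and is
exercised explicitly in tests rather than silently everywhere.

What the simulator deliberately omits: linkage disequilibrium and
recombination (SNPs are independent), demography and drift trajectories,
allele-frequency spectra conditioned on ascertainment, genotyping error,
and structured missingness.  Consequently, passing tests demonstrate that
the statistics, thresholds and bookkeeping behave correctly on data with
the stated frequency structure; they do not certify power or false-positive
rates on real resequencing data, where LD makes neighbouring windows
strongly dependent and background selection can mimic sweeps.

## Numerical and interface choices

- Internal coordinates are 1-based inclusive everywhere (VCF convention);
  BED's 0-based half-open form exists only at file read/write.
- Multi-allelic VCF records are dropped by default (an optional split mode
  keeps the first alternate allele); indels are always dropped; records
  failing FILTER are dropped; phased separators are treated as unphased.
- Quantiles use linear interpolation between order statistics; on 10,000
  tie-free values the strict upper-5% rule selects 500 ± 1 of them.
- Oracle tolerances: scalar-vs-vectorized FST agreement at 1e-12; NJ
  tip-to-tip distance recovery on additive matrices at 1e-9.
- All pipeline randomness flows from one root seed through named
  substreams (simulation, bootstrap, term map), so stages are individually
  reproducible and `run_all` is byte-deterministic for a fixed config.
- Degenerate inputs: empty window → no statistics; all-missing population
  at a SNP → SNP flagged unusable for FST; sample pair with no joint SNPs
  → hard error naming the pair; sweep interval without SNPs → warning,
  truth still emitted.

## Known limitations

- The ratio-of-sums window FST and the per-SNP-mean mode can rank windows
  differently when SNP density varies sharply; only the default is tuned
  by the acceptance checks.
- The literal (non-monotone) FDR can order terms differently from BH when
  p-values cross; significance calls at 0.05 may therefore be
  non-monotone in p. That is a property of the formula, not a bug.
- The enrichment stage ignores term-hierarchy structure (no GO DAG
  propagation) and treats gene identifiers as opaque strings.
- NJ is O(n³) in samples and the IBS matrix O(n²·SNPs); both are fine for
  hundreds of samples but are not engineered beyond that.
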