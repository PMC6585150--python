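# Methods

## The two-library count-comparison test

Expression of a circRNA in one library is its back-splice junction-read
count.  With `x` counts among `N1` total junction reads in library B, the
predictive distribution of the count `y` among `N2` reads in library C,
under the null hypothesis of a common underlying rate and Poisson
sampling, is

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

This is the Audic–Claverie statistic; algebraically it is the
negative-binomial pmf with size `x + 1` and success probability
`1 / (1 + N2/N1)` (a Gamma(x+1, N1) posterior on the rate pushed through
Poisson sampling at depth N2).  The implementation evaluates it in log
space via `gammaln`, so counts up to at least 10^6 are handled without
overflow, and the test suite cross-checks it against exact rational
arithmetic and against an independent negative-binomial implementation.

**Two-sided p-value.**  The point mass itself is not a tail probability,
so the default p-value is the standard two-sided construction
`min(1, 2 · min(P(Y ≤ y | x), P(Y ≥ y | x)))`, with the point mass
retained as `p_mode="point"` for exact reproduction of the formula above.
Tails are finite/convergent sums of the point mass.  Numerically, the
tail on the thin side of the predictive mean `(x+1) · N2/N1` is summed
directly (scaled log-space summation), and the fat side is obtained by
complement; computing the thin side via `1 − cdf` would lose it entirely
to cancellation once it falls below ~1e-16.

**Label symmetry.**  Because the statistic conditions on one of the two
counts, the raw two-sided value is not invariant under exchanging the
samples (e.g. x=1, y=2 at N1=N2 gives 1.0 conditioned on x but 0.625
conditioned on y).  A pairwise comparison should not depend on which
sample is labelled B, so `compare_group` evaluates the tail in a
canonical orientation: it conditions on the smaller count, with ties
broken toward the smaller library.  Swapping B and C then leaves every
p-value bit-identical and only negates log2 ratios and flips directions
(this is asserted by the tests).  `ac_p_value` itself applies no
canonicalization; callers who need the literal conditioned-on-x value get
it.

**Assumptions and calibration.**  The test models sampling noise only
(Poisson); it has no biological-replicate dispersion, which is
appropriate here because each comparison is a single B library against a
single C library.  At low counts the statistic is discrete and therefore
conservative: under a simulated null the fraction of two-sided p < 0.05
sits below the nominal 5–8% band, and the full significance filter
(below) passes ≪ 1% of circRNAs.

## Normalization, filtering, direction

* **TPM** here means junction reads per million total junction reads of
  the sample; the library size `N` is the in-table sum of junction reads
  (an override exists for runs that report a larger per-sample total).
* A circRNA undetected in one sample enters the comparison with count 0
  and TPM floored at 0.001, so log2 ratios are always defined.  The floor
  is applied only to undetected circRNAs, never to detected-but-low ones.
* The log2 ratio is `log2(TPM_C / TPM_B)` — tumor over normal in the
  paired design — computed on TPMs so the 0.001 floor is meaningful.
* FDR control is Benjamini–Hochberg (statsmodels' step-up
  implementation behind the `bh_fdr` surface).  BH adjusted values do not
  depend on the ordering of tied p-values, so no tie-break is needed for
  reproducibility.
* Significance: `FDR < 0.001` and `|log2 ratio| ≥ 1` (defaults; both are
  parameters everywhere, CLI flags `--fdr` / `--min-log2`).
* Direction is Up when TPM_C > TPM_B, otherwise Down.  Equal TPMs are
  reported Down by convention; such rows have log2 ratio 0 and can never
  be significant, so the convention is inert (and tested).
* The per-comparison "diff" count is the number of union circRNAs whose
  TPMs differ; the summary percentile is `100 · n_sig / n_diff` rounded
  half-up to two decimals.

## Region classification and reference matching

A circRNA's span is classified with priority exon > intron > intergenic:
`exon` if it overlaps at least one exon of any gene, else `intron` if it
overlaps at least one gene span, else `intergenic`.  "Overlap" is any
shared base; this is one of several defensible operationalizations (an
alternative would require both junction boundaries to be exonic), chosen
because it is deterministic, partitions every sample, and matches a
per-base brute-force oracle the tests run against random gene models.
Gene attribution takes the gene with the largest exon overlap (falling
back to span overlap), ties broken lexicographically.  Chromosome names
are normalized to a lowercase `chr` prefix so joins are deterministic.

Catalogue matching is by exact interval identity; a slack parameter
(default 0) exists for future tolerant matching, as published catalogues
can disagree by a few bases at junction boundaries.

## Cross-group consistency

Per circRNA, the groups in which it is significant are tallied by
direction.  The consensus direction is the majority; its support `x` out
of `y` total groups is the candidate's `x/y` label.  CircRNAs significant
in both directions ("conflicted", including exact ties) are excluded from
the report and kept separately for audit — recurrence is only meaningful
when the direction agrees.  The reporting threshold defaults to `x ≥ 2`.
Identity across groups is the exact `chrN:start|end` string; no fuzzy
merging.

## The synthetic-data generator

`simulate(SimulationConfig(...))` produces paired (B, C) detection tables
over a shared circRNA universe with known ground truth.

* **Genome / regions.**  A deterministic toy genome (three 100-kb
  chromosomes, genes tiled every 3 kb with four 200-bp exons) hosts the
  universe.  Each circRNA is assigned a true region class
  (91% exon / 8% intron / 1% intergenic, the composition typical of
  back-splice catalogues) and placed so the annotation classifier
  reproduces that class exactly — an internal-consistency contract the
  tests enforce.
* **Abundance.**  Relative baseline rates are log-normal (σ = 1.5, a
  heavy tail typical of junction-count distributions), normalized to sum
  to one, so expected counts are rate × library size.  Library sizes are
  uniform over 5 000–35 000 junction reads by default, the span observed
  across real per-sample junction totals in paired HCC libraries.
* **Counts.**  Negative-binomial with var = m + φm², φ = `dispersion`
  (default 0.01, mild technical-level extra-Poisson noise; 0 gives
  Poisson).  The default is deliberately small: the comparison is a
  within-pair null where biological between-patient variation does not
  enter, and the test itself assumes Poisson sampling.
* **Effects.**  A fraction `frac_de` (default 5%) of circRNAs is truly
  DE; of those, `frac_shared_de` (default 25%) share one signed log2
  fold change across all groups (the recurrent candidates), the rest are
  DE in one random group each.  Tumor-side rates are multiplied by
  2^lfc and renormalized (so realized library sizes track the
  configuration; with ≤ 5% DE the renormalization perturbs planted fold
  changes negligibly).  `shared_de_min_expected_reads` floors the
  baseline rate of shared-DE circRNAs for strong-effect scenarios in
  which every planted candidate is expected at ≥ that many reads.
* **Detection.**  Counts of zero never appear in a table; additionally a
  circRNA with expected count < 1 drops out of a sample with probability
  `detection_dropout` (default 0.3), emulating the partial per-sample
  detection of real data, where per-sample species counts sit well below
  the cross-sample union.
* **Annotation.**  `frac_annotated` (default 0.7, matching the ~65–76%
  catalogue-hit rates of real samples) of the universe enters a synthetic
  reference catalogue with sequential `hsa_circ_XXXXXXX`-style
  accessions.

All randomness flows from one seeded `numpy` generator; a fixed seed
reproduces the dataset byte-for-byte.

What the generator does **not** emulate: real genomic sequence and gene
structure (the toy genome is regular), isoform structure, correlated
effects between circRNAs, batch effects, between-patient biological
dispersion, and mapping artifacts in the SM/MS/SMS alignment signal
(generated as an uninterpreted tag).  Tests passing on synthetic data
therefore validate the statistical machinery and bookkeeping, not the
upstream detection pipeline or the biology of any particular cohort.

## Numerical conventions

* Percentages in summaries are rounded half-up to two decimals (the
  convention of printed summary tables), computed in exact decimal
  arithmetic before rounding.
* Coordinates in `chrN:start|end` identifiers are 1-based inclusive
  (circBase-style); BED export converts to 0-based half-open and caps the
  score at the BED bound of 1000.  Strand is not modelled — the
  detection-table schema has no strand field.
* `junction_reads_ratio`, when absent from an input, is recomputed as
  `2j / (2j + nj)`; a supplied value is preserved and validated for
  [0, 1] only.
* Degenerate inputs: empty detection tables read as zero-record samples;
  a sample with zero total junction reads is rejected from comparisons;
  an empty p-value list adjusts to an empty list; a zero-species sample
  summarizes with 0.00 percentages.

## Problem sizes used in validation

The shipped checks run at desk scale, chosen to make the Monte-Carlo
bounds tight enough to be meaningful while keeping the suite fast: null
calibration uses 2 000 circRNAs at matched 10^5-read libraries over 200
replicate pairs; recovery uses ten seeds of a five-group, 1 000-circRNA
strong-effect scenario (shared-DE baseline ≥ 50 expected reads,
|log2FC| ≥ 2); the default study-scale run uses a 3 000-circRNA universe
over five patient pairs.

## Known limitations

* The test is strictly two-library; replicated designs need dispersion
  estimation (negative-binomial GLMs) and are out of scope.
* "Diff number" (TPMs differ) is one of several possible definitions of
  a differing circRNA between two samples; counts of "differences"
  reported by other tools may not be directly comparable.
* Exact-interval catalogue matching will miss entries whose boundaries
  differ by a few bases; the slack parameter exists but defaults to off.
* The conflicted-candidate exclusion is conservative: a circRNA genuinely
  bidirectional across cohorts is dropped from the headline report (it
  remains available in the audit list).
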