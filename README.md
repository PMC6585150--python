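# circdiff

Differential expression and cross-cohort consistency analysis of circular
RNAs (circRNAs) quantified by back-splice junction reads.

## The problem

CircRNAs are covalently closed transcripts whose 3′ and 5′ ends are joined
by back-splicing.  A circRNA is identified by its junction coordinates
(written `chrN:start|end`, the donor and acceptor sites) and its expression
in a sample is measured by the number of sequencing reads spanning the
head-to-tail junction.  Given detection tables from paired samples — e.g.
tumor tissue and adjacent normal tissue from the same patient — the
questions are: which circRNAs change between the two conditions, and which
of those changes recur, in the same direction, across several patients?
Recurrent same-direction changes are candidate disease-associated
circRNAs; those without an entry in a circBase-style catalogue are novel.

`circdiff` is a library plus CLI for this workflow, aimed at
bioinformaticians working from per-sample circRNA detection tables (it
does not do read alignment or back-splice detection).

## The method

For one circRNA with `x` junction reads among `N1` total junction reads in
sample B and `y` among `N2` in sample C, the two-library count-comparison
statistic (Audic–Claverie) is the predictive probability

```
p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )
```

i.e. the negative-binomial pmf with size `x+1` and success probability
`1/(1 + N2/N1)`.  The default p-value doubles the smaller predictive tail
(two-sided); the raw point mass is available as `p_mode="point"`.  Within a
comparison, p-values over the union of detected circRNAs are
Benjamini–Hochberg adjusted.  Expression is normalized to TPM (junction
reads per million total junction reads) with a floor of 0.001 for
undetected circRNAs, and a circRNA is called significant when
`FDR < 0.001` and `|log2(TPM_C / TPM_B)| >= 1` (both configurable).

Across several comparison groups, significant calls are aggregated per
circRNA: a candidate found significant in the same direction in `x` of `y`
groups is reported with the label `x/y` (default threshold: at least 2
groups; circRNAs significant Up in some groups and Down in others are
excluded).  Candidates are split into catalogue-annotated and novel.

The package also includes region classification (exon / intron /
intergenic, from a GTF/GFF or simplified gene-model table), per-sample
summary statistics, and a synthetic-data generator that produces paired
tumor/normal detection tables with known ground truth for validation.

## Worked example

```python
from circdiff import (SimulationConfig, simulate, compare_group, aggregate,
                      split_annotated, truth_eval)

cfg = SimulationConfig(n_circ=1000, n_groups=5, frac_de=0.05,
                       frac_shared_de=0.3, log2fc_range=(2.0, 3.0),
                       shared_de_min_expected_reads=50.0, seed=1)
groups, gene_model, reference, truth = simulate(cfg)

per_group = {}
for grp in groups:
    results, summary = compare_group(grp)          # FDR < 0.001, |log2 ratio| >= 1
    per_group[grp.group_id] = results
    print(f"{summary.group_id}: diff={summary.n_diff} "
          f"significant={summary.n_sig} ({summary.percentile}%)")

report = aggregate(per_group, min_groups=2)
annotated, novel = split_annotated(report)
print(f"{len(report.records)} recurrent candidates "
      f"({len(annotated)} annotated, {len(novel)} novel)")
for rec in report.records[:3]:
    print(f"  {rec.circ_id}  {rec.circbase_id or '-'}  "
          f"{rec.consensus_direction}  {rec.found_label}")

metrics = truth_eval(report, truth)
print(f"shared-DE recall at 5/5: {metrics.recall(5):.2f}, "
      f"direction accuracy: {metrics.direction_accuracy:.2f}")
```

Output:

```
1B_vs_1C: diff=906 significant=18 (1.99%)
2B_vs_2C: diff=854 significant=17 (1.99%)
3B_vs_3C: diff=951 significant=17 (1.79%)
4B_vs_4C: diff=948 significant=20 (2.11%)
5B_vs_5C: diff=875 significant=15 (1.71%)
15 recurrent candidates (11 annotated, 4 novel)
  chr1:1117|2408  hsa_circ_0000690  Down  5/5
  chr1:30541|32451  hsa_circ_0000059  Up  5/5
  chr1:30728|30810  hsa_circ_0000382  Up  5/5
shared-DE recall at 5/5: 1.00, direction accuracy: 1.00
```

Five simulated patients each contribute a (normal B, tumor C) pair; in
every pair roughly 900 circRNAs differ in normalized expression, of which
~2% survive the FDR and fold-change filter.  Fifteen circRNAs recur with a
consistent direction in at least two patients; the candidates planted by
the generator as shared across all five patients are all recovered at
`5/5` with the planted direction.

The same workflow is available from the shell:

```
circdiff simulate --out data            # synthetic dataset + ground truth
circdiff summarize data/1B.tsv data/1C.tsv \
    --gene-model data/gene_model.tsv --reference data/reference.tsv --out summ
circdiff compare data/1B.tsv data/1C.tsv --fdr 0.001 --min-log2 1 --out cmp1
circdiff aggregate cmp*/results.tsv --min-groups 2 --out agg
```

Every command writes a `manifest.json` with parameters and input
checksums so runs are reproducible.

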