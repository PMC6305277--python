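# txcontext

Transcript- and tissue-context interpretation of protein-coding variants.

A genomic variant does not have *one* protein-coding consequence — it has one
per transcript. The same G>A change can introduce a premature stop codon in
one isoform, a missense substitution in a second whose alternative splice
boundary shifts the reading frame, and fall in an intron or 5'UTR of a third.
Which consequence matters further depends on which isoform is actually
expressed in the tissue of interest. `txcontext` quantifies both layers of
context on synthetic cohorts with planted, machine-verifiable truth:

* **per-transcript consequence annotation** with a four-level impact
  taxonomy — HIGH (alteration to coding length or frame, including the ±2 bp
  splice sites), MODERATE (missense, in-frame indels), LOW (silent,
  splice-region), MODIFIER (non-coding);
* **transcript-affected genes** — genes where at least one (e.g. pathogenic)
  variant has different impact classes across the gene's transcripts, with a
  Pearson χ² comparison of the affected proportion across significance
  classes (PATHOGENIC / VUS / BENIGN, derived from multi-submitter
  ClinVar-style assertion records);
* **expression-affected genes** — genes whose most highly expressed
  transcript satisfies, conjunctively: expression summary ≥ 80th percentile
  of genes, one-way inter-tissue ANOVA *p* < 10⁻³⁰, and
  MS_between / MS_within ≥ 10 (on log₂(TPM+1));
* **gene-set burden** — for pathway and disease collections, the fraction of
  in-universe member genes carrying a flag, with the mean fraction and the
  counts of sets affected for ≥ 25% / ≥ 50% of their genes;
* **network context** — the affected-gene subgraph of a protein-interaction
  network summarized by its degree-distribution power-law exponent γ
  (discrete maximum likelihood, x_min = 1: the degree counts decay as
  x^(−γ)), mean shortest-path betweenness and edge density, compared with a
  seeded random-gene resampling null (add-one two-sided empirical p).

Every input the pipeline consumes can be generated synthetically with
planted truth: genes whose isoform structures encode the three divergence
motifs (exon skipping, frame-shifting alternative splice boundary,
downstream coding start), submitter patterns that classify
deterministically, tissue-shifted expression, gene sets with exact affected
fractions, and configuration-model scale-free networks with optional
degree-biased gene sets. A deliberately naive oracle annotator (chromosome
mutation, coordinate shifting, re-translation) validates every planted
expectation and the fast annotator itself.

## Worked example

```bash
python analysis/01_simulate_data.py --seed 1       # inputs -> results/bundle/
python analysis/02_annotate_variants.py --seed 1
python analysis/03_transcript_affected_genes.py --seed 1
python analysis/04_expression_affected_genes.py --seed 1
python analysis/05_pathway_disease_burden.py --seed 1
python analysis/06_network_context.py --seed 1
```

prints (seed 1):

```
3074 consequence calls written to results/annotation.tsv
  HIGH         149  (4.8%)
  MODERATE     261  (8.5%)
  LOW          133  (4.3%)
  MODIFIER    2531  (82.3%)

per-class gene counts (affected / with variants):
  PATHOGENIC  51 /  60 genes (404 records)
  VUS         39 /  60 genes (358 records)
  BENIGN      33 /  59 genes (238 records)
chi-squared: statistic 12.272, p 0.00216, max proportion difference 0.291
planted-truth recovery exact: True

expression-affected genes: 10 / 60
overlap with transcript-affected (PATHOGENIC): 9 genes = 90% of the smaller set

pathways:
  transcript_PATHOGENIC  mean fraction  47.2%  >=25%: 9/12 sets  >=50%: 6/12 sets
```

Reading: 404 pathogenic-classified records hit 60 genes; in 51 of them the
impact class differs between isoforms for at least one pathogenic variant,
a significantly higher proportion than for benign variants (χ² p ≈ 0.002,
max proportion difference 0.29). Ten genes pass all three
expression criteria (the generator planted twelve); nine of the ten are
also transcript-affected. Of the twelve planted pathway sets, nine have at
least a quarter, and six at least half, of their genes transcript-affected —
exactly the fractions the generator planted, which is the point: every
number above is checkable against `results/bundle/truth.json`.

The same stages are available as a CLI (`txcontext simulate|annotate|
flag-transcripts|flag-expression|burden|network|run-all`); `run-all` writes
a single JSON report whose body is byte-identical across runs with the same
inputs and seed.

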