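# Methods

## Consequence model

A variant is a VCF-style anchored allele replacement on a chromosome
(1-based position, non-empty REF/ALT over ACGT). Normalization trims shared
context and left-aligns indels; the annotator requires normalized input and
is idempotent under it.

Positional rules are evaluated on the *changed* bases of the normalized
variant: the shared anchor base of an anchored indel is not changed, and a
pure insertion is carried by its anchor base, its inserted material sitting
immediately before the spliced base that follows it in transcript
orientation. An insertion anchored at the last base of an exon is absorbed
into that exon (exon boundaries at or past the edit shift through it), i.e.
treated as an exonic coding insertion. These conventions are applied
identically in the fast annotator and in the validation oracle; without
them, anchored deletions that merely *touch* a boundary with their anchor
would be misattributed to the neighbouring region.

The decision tree per (variant, transcript):

1. outside the transcript → upstream/downstream within a 5 kb flank on
   either side (a common annotator convention; the generator spaces genes
   ≥ 10 kb so flanks never overlap neighbours), else intergenic;
2. changed bases within the 2 intronic bases flanking a CDS-overlapping
   exon → splice_donor / splice_acceptor (HIGH);
3. intronic bases 3–8 or exonic bases 1–3 from such a junction mark a
   splice-region candidate (LOW), reported only when no more severe coding
   term applies;
4. exonic in a non-coding transcript → non_coding_transcript_variant;
5. entirely 5'/3'UTR → the UTR terms;
6. CDS-overlapping → the mutant spliced transcript is rebuilt, both
   sequences translated from the CDS start to the first stop (standard
   nuclear code), and the proteins compared: a disrupted start codon is
   start_lost (checked first, so ATG→TAG is start_lost rather than
   stop_gained); a net length change not divisible by 3 is a frameshift;
   identical proteins are synonymous (stop_retained when the change sits in
   the stop codon); otherwise the position of the first stop relative to
   its in-frame expectation decides stop_gained / stop_lost, then in-frame
   indels and missense. Transcripts whose annotated CDS is not a whole
   number of codons, or does not begin with ATG, yield calls marked
   `low_confidence`.

Impact classes are a fixed function of the effect term: HIGH =
{stop_gained, stop_lost, start_lost, frameshift, splice_donor,
splice_acceptor}; MODERATE = {missense, in-frame indels}; LOW =
{synonymous, stop_retained, splice_region}; MODIFIER = everything else.

c./p. labels follow HGVS conventions (`c.1716+19C>T`, `p.Gln579*`,
`p.Gly1255Glu`) without full HGVS edge-case compliance (no 3'-rule for
protein duplications); intronic offsets attach to the donor side up to the
intron midpoint (ties to the donor), then to the acceptor side.

### The validation oracle

`txcontext.oracle` re-derives every call naively and independently: it
applies the edit to the chromosome sequence itself, shifts every exon and
CDS coordinate through the edit (coordinates inside a deleted span snap to
the edit point), re-extracts and re-translates the mutant transcript, and
evaluates positional rules on explicit sets of genomic positions. The two
routes share the effect taxonomy and its decision order — a taxonomy is a
convention, not a computation — but no coordinate arithmetic or sequence
machinery, which is where annotators actually fail. The acceptance suite
requires exact agreement of effect term and impact class for every
CDS-overlapping SNV, every 1–6 bp deletion, and 1–6 bp insertions with
interior anchors (alternating positions, covering both frames), on a
50-gene genome with 2–4 transcripts per gene and both strands (~500,000
comparisons). Insertions anchored exactly at a CDS edge base are a pure
convention corner (which side "owns" the insert) and both routes implement
the slot convention above.

## Significance classes

A record is retained only if at least one submitter provides manually
curated assertion criteria. Retained records map to exactly one class:
PATHOGENIC when every non-`other` submission is (likely) pathogenic with at
least one such submission; VUS on any `uncertain` submission or any
conflict across the pathogenic/benign divide; BENIGN when all submissions
are (likely) benign *and* at least one is the full `benign` label —
likely_benign-only records are excluded rather than folded into VUS, the
literal reading of the inclusion rule; everything else is excluded. The
proportion test is a Pearson χ² on the affected/unaffected × class table
without continuity correction (the stated test is the uncorrected χ², and
at cohort sizes of hundreds of genes the correction is immaterial); the
effect size is the maximum pairwise difference in proportions, one natural
reading of a "difference in proportions" effect measure.

A gene is transcript-affected for a class when at least one variant of that
class shows ≥ 2 distinct impact classes across the gene's whitelisted
transcripts (biotypes: protein_coding, nonsense_mediated_decay,
retained_intron, processed_transcript; unknown biotypes map to `other` and
are filtered, not errors). The comparison is at impact level, not effect
level: a stop_gained/frameshift pair (both HIGH) does not flag a gene.

## Expression classifier

All computation is on log₂(TPM+1); variance stabilization makes the 10×
mean-square ratio comparable across abundance ranges. Per gene, the top
transcript maximizes the mean log value over all samples (ties:
lexicographically smallest id, so runs are reproducible). The gene summary
is that transcript's mean log value; percentile ranks are computed over all
genes in the matrix. The one-way fixed-effects ANOVA exposes
MS_between = Σ n_t(x̄_t − x̄)²/(T−1) and MS_within = Σ(x_ts − x̄_t)²/(N−T);
p is the upper F tail with (T−1, N−T) df; a zero within-group mean square is
flagged degenerate (p = 0 if any between-group signal, else p = 1). The
three criteria (≥ 80th percentile, p < 10⁻³⁰, ratio ≥ 10) are conjunctive.
p-values are deliberately not multiplicity-adjusted: the fixed extreme
threshold is the control. The ratio is implemented as MS_between/MS_within
(the F statistic's components); a config option is not provided for the
alternative raw-variance reading because the mean-square ratio is the only
one with the F statistic's sampling theory behind it.

Note a structural consequence of the percentile criterion: at most ~20% of
the genes in a matrix can ever be flagged, so planted fractions above 0.2
cannot be fully recovered (the generator rejects > 0.5 outright).

## Burden and overlap

Fractions are computed over each set's members intersected with the
analysis universe (genes with annotation or expression results); unmeasured
genes cannot be classified either way and would bias fractions toward
zero. Sets with no in-universe member are excluded from summaries.
Threshold counts use inclusive comparisons (≥ 0.25, ≥ 0.50); the collection
mean is unweighted over scored sets. Overlap between the transcript- and
expression-affected sets reports the intersection with all three candidate
percentage denominators (smaller set — the headline —, union, larger set),
since published overlap percentages rarely state their base.

## Network context

Graphs are simple and undirected (self-loops and duplicate edges dropped,
idempotently). The degree exponent uses the exact discrete power-law MLE at
x_min = 1: γ̂ maximizes −n·ln ζ(γ, x_min) − γ·Σ ln dᵢ over degrees dᵢ ≥ 1
(Hurwitz ζ; bounded scalar optimization on [1.01, 8]; degree-0 nodes are
excluded — they carry no power-law information — and a fit requires ≥ 10
nonzero-degree nodes). The widely quoted closed-form approximation
1 + n[Σ ln(dᵢ/(x_min−½))]⁻¹ is available as `method="approx"` but is
*severely* biased at x_min = 1 (zipf γ=2.7 samples fit near 2.1) and should
only be used with larger x_min; a log–log least-squares histogram fit is the
second alternative. Betweenness is exact unweighted shortest-path
betweenness (unnormalized, averaged over nodes); density is |E|/(|V|·(|V|−1)/2).

The null resamples k genes uniformly without replacement from a candidate
pool (protein-coding network nodes), summarizes each induced subgraph, and
reports per-metric mean, sd, z-score and the add-one two-sided empirical
p = (1 + #{|rep − mean| ≥ |obs − mean|})/(n + 1); 100 replicates by
default. Replicates whose subgraph cannot support a γ fit are excluded from
that metric's null (the empirical p denominator follows the usable count).
Nulls are bit-reproducible given (network, k, replicates, seed). Two
networks configured together are analyzed independently, never merged.

## Synthetic data

Generators are pure functions of (parameters, seed); one top-level seed
derives fixed per-generator substreams (`SeedSequence(seed, spawn_key)`), so
adding a generator never perturbs another's output.

**Genome.** Default 3 chromosomes; genes placed alternately with ≥ 10 kb
spacers; 3–5 exons of ≥ 10 codons each with internal boundaries on codon
multiples; 60–120 codons of CDS (start + non-stop codons + stop); introns
80–200 bp; strands random. A configurable fraction of genes (default 0.6)
carries one of three divergence motifs with a planted CAA codon whose C>T
witness is stop_gained in the canonical isoform: (a) the exon carrying it is
skipped in an alternative isoform (witness intronic there), (b) an
alternative acceptor one base into the intron shifts the downstream frame
(witness missense/other in the shifted frame; a stop for the shifted frame
is planted in the 3'UTR), (c) an internal ATG becomes a downstream coding
start (witness 5'UTR in that isoform). Every witness's per-transcript
impacts are verified with the oracle at generation time and recorded; the
rare frame-shift motif whose shifted-frame consequence happens to match the
canonical impact is demoted to non-divergent rather than retried.

**Cohort.** Witness variants are always PATHOGENIC; remaining variants
(SNVs plus 1–3 bp indels) draw a class from the configured mix
(default 0.4/0.35/0.25) and a submitter pattern that classifies
deterministically (asserted at generation). The per-class
transcript-affected truth is computed with the oracle-validated annotator
itself, which is what makes downstream recovery exact by construction.

**Expression.** log₂ abundance = transcript baseline (gene baseline
N(3, 2); minor transcripts 1–3 log₂ lower) + gene-level tissue shift
(planted genes: +6 log₂ in a random 1–3 tissue subset) + N(0, 0.5) noise;
planted genes draw baselines from the top quintile so the percentile
criterion is satisfiable; TPM is emitted as 2^x − 1 clipped at 0 so the log
transform round-trips. The planted-recovery experiment (1,000 genes, 100
planted, 10 tissues × 20 samples) reflects the magnitude of strong
tissue-enrichment signals; what it does not emulate — shared covariance
between tissues, batch structure, zero inflation, transcript-level
switching within a gene — means a pass demonstrates the classifier's
arithmetic and thresholds, not robustness to real expression artifacts.

**Gene sets.** Each set samples ⌈f·s⌉ affected and s − ⌈f·s⌉ unaffected
genes for a target fraction ladder (pathways {0, .25, .5, 1}, diseases
{0, .5, .75, 1}), so realized fractions are exact by construction;
infeasible targets raise, naming the set.

**Network.** Degrees are zipf(γ) draws capped at √n (the natural cutoff —
without it multi-edge collapse in the configuration model flattens the
realized tail), paired by the configuration model, simplified; an odd
degree sum increments the smallest degree (recorded). Optional hub genes
receive the largest degrees; the full bundle wires the planted
expression-affected genes as hubs, so the end-to-end network stage shows
the flatter-exponent/denser-subgraph contrast. Exponent recovery holds at
|γ̂ − γ| ≤ 0.15 for γ ∈ {2.2, 2.7, 3.5} at n = 2,000 across 20 seeds.

## Pipeline and problem sizes

`run_all` executes annotate → classify → transcript flags → expression
flags → overlap → burden → network, skipping unconfigured stages, and
produces a report whose JSON body (provenance timestamp excluded) is
byte-identical across runs with the same inputs, config and seed. All fixed
constants (80th percentile, 10⁻³⁰, 10×, 0.25/0.50, the biotype whitelist,
splice windows, replicate counts) live in `AnalysisConfig` / YAML, so
threshold sensitivity analyses need no code change.

Default study sizes were chosen so every planted structure is represented
with margin while the whole analysis, test suite and acceptance script each
complete in minutes on a single CPU: 60 genes × 2–4 transcripts and 1,000
cohort variants for the pipeline bundle; 50 genes for the exhaustive
dual-route scan (~5×10⁵ comparisons); 1,000 genes for expression recovery;
2,000 network nodes for exponent recovery and 1,000 for the 20–50-repetition
null-direction experiments.

## Known limitations

* Splice consequences are positional only; no splice-strength scoring, no
  prediction of splice-altering variants outside the fixed windows, and no
  NMD modeling (NMD-biotype transcripts are annotated by the same rules).
* MNVs are block substitutions; separate nearby variants are not
  codon-phased.
* The annotator assumes biallelic records (multi-allelic VCF rows are split
  on input).
* Gene-level tissue shifts mean the generator never plants isoform
  *switching* between tissues; the top-transcript choice is therefore
  global, as in the analysis it supports.
* γ̂ at x_min = 1 measures the whole degree distribution; no x_min scanning
  à la goodness-of-fit selection is performed.
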