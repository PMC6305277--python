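"""Variant normalization, impact taxonomy, and the consequence decision tree.

The deep check is dual-route: the fast annotator (spliced-coordinate
arithmetic) against the naive oracle (chromosome mutation + coordinate
shifting + re-translation) over exhaustive SNV/indel scans; the case
fixtures pin the published label styles.
"""

import pytest

from txcontext.consequence import (
    ConsequenceCall,
    EffectTerm,
    ImpactClass,
    Variant,
    annotate_gene,
    consequence_for_transcript,
    impact_of,
    normalize,
    read_vcf,
    write_annotated_vcf,
)
from txcontext.gene_models import DEFAULT_BIOTYPE_WHITELIST, Biotype, GenomeSequence
from txcontext.oracle import oracle_consequence


# ---------------------------------------------------------------- normalize
def test_normalize_trims_shared_prefix():
    g = GenomeSequence({"c": "T" * 9 + "CATTTTTTTT"})
    v = normalize(Variant(chrom="c", pos=10, ref="CA", alt="CT"), g)
    assert (v.pos, v.ref, v.alt) == (11, "A", "T")


def test_normalize_left_aligns_homopolymer_deletion():
    #            123456789
    g = GenomeSequence({"c": "GCAAAATGC"})
    for pos, ref in [(5, "AA"), (4, "AA"), (3, "AA")]:
        v = normalize(Variant(chrom="c", pos=pos, ref=ref, alt=ref[0]), g)
        assert (v.pos, v.ref, v.alt) == (2, "CA", "C")


def test_normalize_idempotent_and_checks_ref():
    g = GenomeSequence({"c": "GCAAAATGC"})
    v = normalize(Variant(chrom="c", pos=5, ref="AAT", alt="A"), g)
    assert normalize(v, g) == v
    with pytest.raises(ValueError, match="ref mismatch"):
        normalize(Variant(chrom="c", pos=1, ref="T", alt="A"), g)


# ----------------------------------------------------------------- impacts
@pytest.mark.parametrize(
    "effect,impact",
    [
        (EffectTerm.STOP_GAINED, ImpactClass.HIGH),
        (EffectTerm.STOP_LOST, ImpactClass.HIGH),
        (EffectTerm.START_LOST, ImpactClass.HIGH),
        (EffectTerm.FRAMESHIFT, ImpactClass.HIGH),
        (EffectTerm.SPLICE_ACCEPTOR, ImpactClass.HIGH),
        (EffectTerm.SPLICE_DONOR, ImpactClass.HIGH),
        (EffectTerm.MISSENSE, ImpactClass.MODERATE),
        (EffectTerm.INFRAME_INSERTION, ImpactClass.MODERATE),
        (EffectTerm.INFRAME_DELETION, ImpactClass.MODERATE),
        (EffectTerm.SYNONYMOUS, ImpactClass.LOW),
        (EffectTerm.STOP_RETAINED, ImpactClass.LOW),
        (EffectTerm.SPLICE_REGION, ImpactClass.LOW),
        (EffectTerm.INTRON, ImpactClass.MODIFIER),
        (EffectTerm.UTR5, ImpactClass.MODIFIER),
        (EffectTerm.UTR3, ImpactClass.MODIFIER),
        (EffectTerm.UPSTREAM, ImpactClass.MODIFIER),
        (EffectTerm.DOWNSTREAM, ImpactClass.MODIFIER),
        (EffectTerm.NON_CODING_TRANSCRIPT, ImpactClass.MODIFIER),
        (EffectTerm.INTERGENIC, ImpactClass.MODIFIER),
    ],
)
def test_impact_table(effect, impact):
    assert impact_of(effect) is impact


# ------------------------------------------------------------ case fixtures
def _calls(fx):
    return annotate_gene(fx["variant"], fx["gene"], fx["genome"], DEFAULT_BIOTYPE_WHITELIST)


def test_three_isoform_fixture_spans_three_impact_classes(fixtures):
    calls = _calls(fixtures["fig"])
    assert {c.impact for c in calls} == {
        ImpactClass.HIGH,
        ImpactClass.MODERATE,
        ImpactClass.MODIFIER,
    }
    by_tx = {c.transcript_id: c for c in calls}
    assert by_tx["GFIG.T1"].effect is EffectTerm.STOP_GAINED
    assert by_tx["GFIG.T2"].effect is EffectTerm.MISSENSE
    assert by_tx["GFIG.T3"].effect is EffectTerm.INTRON


def test_nonsense_in_long_isoform_intronic_in_short(fixtures):
    calls = {c.transcript_id: c for c in _calls(fixtures["chd7_like"])}
    long_call, short_call = calls["GCHD.T1"], calls["GCHD.T2"]
    assert long_call.effect is EffectTerm.STOP_GAINED
    assert long_call.protein_label == "p.Gln579*"
    assert short_call.effect is EffectTerm.INTRON
    assert short_call.cdna_label == "c.1716+19C>T"


def test_missense_in_canonical_skipped_in_alternative(fixtures):
    calls = {c.transcript_id: c for c in _calls(fixtures["arid1a_like"])}
    assert calls["GARI.T1"].effect is EffectTerm.MISSENSE
    assert calls["GARI.T1"].protein_label == "p.Gly1255Glu"
    assert calls["GARI.T2"].impact is ImpactClass.MODIFIER


def test_nonsense_in_canonical_utr_in_downstream_start_isoform(fixtures):
    calls = {c.transcript_id: c for c in _calls(fixtures["kmt2c_like"])}
    assert calls["GKMT.T1"].effect is EffectTerm.STOP_GAINED
    assert calls["GKMT.T2"].effect is EffectTerm.UTR5
    assert calls["GKMT.T2"].impact is ImpactClass.MODIFIER


def test_third_position_synonymous(fixtures):
    # GGA -> GGG at codon 1255 third position: silent
    fx = fixtures["arid1a_like"]
    v = Variant(chrom="chrARI", pos=3995, ref="A", alt="G")
    call = consequence_for_transcript(v, fx["gene"].transcripts[0], fx["genome"])
    assert call.effect is EffectTerm.SYNONYMOUS
    assert call.impact is ImpactClass.LOW


# ------------------------------------------------------------ annotate_gene
def test_annotate_gene_filters_biotypes(fixtures):
    fx = fixtures["fig"]
    assert len(_calls(fx)) == 3
    only_pc = annotate_gene(
        fx["variant"], fx["gene"], fx["genome"], {Biotype.PROTEIN_CODING}
    )
    assert len(only_pc) == 3  # all three isoforms are protein_coding
    with pytest.raises(ValueError, match="empty biotype whitelist"):
        annotate_gene(fx["variant"], fx["gene"], fx["genome"], set())


def test_upstream_variant_is_modifier_for_all_transcripts(fixtures):
    fx = fixtures["fig"]
    v = Variant(chrom="chrFIG", pos=20, ref="T", alt="A")
    calls = annotate_gene(v, fx["gene"], fx["genome"], DEFAULT_BIOTYPE_WHITELIST)
    assert all(c.impact is ImpactClass.MODIFIER for c in calls)
    assert all(c.effect is EffectTerm.UPSTREAM for c in calls)


def test_calls_are_ordered_by_transcript_id(fixtures):
    calls = _calls(fixtures["fig"])
    assert [c.transcript_id for c in calls] == sorted(c.transcript_id for c in calls)


# -------------------------------------------------------- oracle equivalence
def _scan_variants(genome, gene, dels=(1, 3), ins=("AG",)):
    chrom_seq = genome[gene.chrom]
    cds_pos = set()
    for t in gene.transcripts:
        if not t.is_coding:
            continue
        for e in t.exons:
            cds_pos.update(range(max(e.start, t.cds_start), min(e.end, t.cds_end)))
    for p in sorted(cds_pos):
        ref = chrom_seq[p]
        for alt in "ACGT":
            if alt != ref:
                yield Variant(chrom=gene.chrom, pos=p + 1, ref=ref, alt=alt)
        for k in dels:
            if p >= 1:
                r = chrom_seq[p - 1 : p + k]
                yield Variant(chrom=gene.chrom, pos=p, ref=r, alt=r[0])
        for extra in ins:
            yield Variant(chrom=gene.chrom, pos=p + 1, ref=ref, alt=ref + extra)


def test_oracle_equivalence_on_sampled_genes(small_genome):
    """Effect term and impact of every CDS-overlapping SNV and small indel
    match naive mutant re-translation, on both strands."""
    genome, genes, _ = small_genome
    strands = set()
    n = 0
    for gene in genes[:4]:
        strands.update(t.strand for t in gene.transcripts)
        for v in _scan_variants(genome, gene):
            v = normalize(v, genome)
            for tx in gene.transcripts:
                call = consequence_for_transcript(v, tx, genome)
                o_effect, o_impact = oracle_consequence(v, tx, genome)
                assert (call.effect, call.impact) == (o_effect, o_impact), (
                    str(v),
                    tx.transcript_id,
                )
                assert call.impact is impact_of(call.effect)
                n += 1
    assert n > 5000


def test_severity_monotonicity(small_genome):
    """A stop-introducing SNV is never classified below HIGH; a
    protein-identical change never above LOW."""
    from txcontext.gene_models import CODON_TABLE, cds_sequence

    genome, genes, _ = small_genome
    checked = 0
    for gene in genes:
        if checked > 500:
            break
        for tx in gene.transcripts:
            if not tx.is_coding or tx.strand != "+":
                continue
            cds = cds_sequence(tx, genome)
            lo, _ = tx.cds_spliced_interval
            # only codons strictly before the transcript's own first stop:
            # a "stop" created beyond it never reaches translation
            from txcontext.gene_models import translate

            n_translated = len(translate(cds[: len(cds) - len(cds) % 3]))
            for ci in range(1, min(n_translated - 1, 40)):
                codon = cds[3 * ci : 3 * ci + 3]
                for j in range(3):
                    for b in "ACGT":
                        if b == codon[j]:
                            continue
                        mut = codon[:j] + b + codon[j + 1 :]
                        gpos = tx.spliced_to_genomic(lo + 3 * ci + j)
                        v = Variant(chrom=tx.chrom, pos=gpos + 1, ref=codon[j], alt=b)
                        call = consequence_for_transcript(v, tx, genome)
                        if CODON_TABLE[mut] == "*" and CODON_TABLE[codon] != "*":
                            assert call.impact is ImpactClass.HIGH
                        if CODON_TABLE[mut] == CODON_TABLE[codon]:
                            assert call.impact in (ImpactClass.LOW, ImpactClass.MODIFIER)
                        checked += 1
    assert checked > 100


# ------------------------------------------------------------------ VCF I/O
def test_vcf_round_trip(tmp_path, fixtures):
    fx = fixtures["fig"]
    calls = _calls(fx)
    path = tmp_path / "out.vcf"
    write_annotated_vcf(
        [(fx["variant"], calls)], {"chrFIG": fx["genome"].length("chrFIG")}, path
    )
    variants = read_vcf(path)
    assert variants == [fx["variant"]]
    assert "TXC=" in path.read_text()


def test_variant_validation():
    with pytest.raises(ValueError):
        Variant(chrom="c", pos=0, ref="A", alt="T")
    with pytest.raises(ValueError):
        Variant(chrom="c", pos=1, ref="A", alt="A")
    with pytest.raises(ValueError):
        Variant(chrom="c", pos=1, ref="", alt="A")
    with pytest.raises(ValueError):
        Variant(chrom="c", pos=1, ref="N", alt="A")


def test_consequence_call_invariant(fixtures):
    for fx in fixtures.values():
        for call in _calls(fx):
            assert isinstance(call, ConsequenceCall)
            assert call.impact is impact_of(call.effect)
            coding = call.effect in {
                EffectTerm.STOP_GAINED,
                EffectTerm.STOP_LOST,
                EffectTerm.START_LOST,
                EffectTerm.MISSENSE,
                EffectTerm.SYNONYMOUS,
                EffectTerm.STOP_RETAINED,
                EffectTerm.FRAMESHIFT,
                EffectTerm.INFRAME_INSERTION,
                EffectTerm.INFRAME_DELETION,
            }
            assert (call.protein_label is not None) == coding
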