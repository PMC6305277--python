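"""Genome/transcript data structures, I/O round-trips, and coordinate maps."""

import pytest
from Bio.Seq import Seq

from txcontext.gene_models import (
    Biotype,
    ExonInterval,
    GenomeSequence,
    ParseError,
    Region,
    TranscriptModel,
    TranslationWarning,
    cds_sequence,
    map_genomic_position,
    read_fasta,
    read_gtf,
    reverse_complement,
    spliced_sequence,
    translate,
    write_fasta,
    write_gtf,
)


# ---------------------------------------------------------------- FASTA
def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nACGT\n")
    g = read_fasta(p)
    assert g.chromosomes == {"chr1": "ACGT"}


def test_read_fasta_case_normalized_and_wrapped(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nacg\nt\n>chr2\nTTAA\n")
    g = read_fasta(p)
    assert g["chr1"] == "ACGT"
    assert g["chr2"] == "TTAA"


def test_read_fasta_empty_is_error(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    with pytest.raises(ParseError, match="no records"):
        read_fasta(p)


def test_fasta_round_trip(tmp_path, small_genome):
    genome, _, _ = small_genome
    p = tmp_path / "rt.fa"
    write_fasta(genome, p)
    assert read_fasta(p).chromosomes == genome.chromosomes


def test_genome_bounds_checked():
    g = GenomeSequence({"c": "ACGT"})
    assert g.fetch("c", 1, 3) == "CG"
    with pytest.raises(IndexError):
        g.fetch("c", 2, 5)
    with pytest.raises(KeyError):
        g["missing"]


# ---------------------------------------------------------------- GTF
GTF = """\
chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "g1"; gene_name "G1";
chr1\tsrc\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t301\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tCDS\t151\t200\t.\t+\t0\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; transcript_biotype "weird_biotype";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; transcript_biotype "weird_biotype";
"""


def test_read_gtf_structure_and_coordinates(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(GTF)
    genes = read_gtf(p)
    assert len(genes) == 1
    gene = genes[0]
    assert len(gene.transcripts) == 2
    t1 = {t.transcript_id: t for t in gene.transcripts}["t1"]
    # 1-based [101,200] -> 0-based half-open [100,200)
    assert t1.exons[0] == ExonInterval(100, 200)
    assert (t1.cds_start, t1.cds_end) == (150, 400)
    t2 = {t.transcript_id: t for t in gene.transcripts}["t2"]
    assert t2.biotype is Biotype.OTHER
    assert not t2.is_coding


def test_read_gtf_missing_attribute_is_error(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text('chr1\tsrc\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
    with pytest.raises(ParseError, match="transcript_id"):
        read_gtf(p)


def test_read_gtf_exon_outside_transcript_span(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\tsrc\ttranscript\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tsrc\texon\t90\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(ParseError, match="outside declared transcript range"):
        read_gtf(p)


def test_gtf_round_trip(tmp_path, small_genome):
    _, genes, _ = small_genome
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_gtf(genes, p1)
    reread = read_gtf(p1)
    write_gtf(reread, p2)
    assert p1.read_text() == p2.read_text()
    assert [g.gene_id for g in reread] == [g.gene_id for g in genes]
    for g1, g2 in zip(genes, reread):
        for t1, t2 in zip(g1.transcripts, g2.transcripts):
            assert t1 == t2


# ------------------------------------------------------- sequence extraction
def _tx(exons, strand="+", cds=None, biotype=Biotype.PROTEIN_CODING):
    return TranscriptModel(
        transcript_id="t",
        gene_id="g",
        chrom="c",
        strand=strand,
        exons=tuple(ExonInterval(*e) for e in exons),
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
        biotype=biotype,
    )


def test_spliced_sequence_concatenates_exons():
    g = GenomeSequence({"c": "ATGCCCAAATTT"})
    tx = _tx([(0, 3), (6, 9)])
    assert spliced_sequence(tx, g) == "ATGAAA"


def test_spliced_sequence_minus_strand_reverse_complements():
    g = GenomeSequence({"c": "ATGC"})
    tx = _tx([(0, 4)], strand="-")
    assert spliced_sequence(tx, g) == "GCAT"


def test_spliced_sequence_beyond_chromosome_errors():
    g = GenomeSequence({"c": "ATGC"})
    tx = _tx([(0, 8)])
    with pytest.raises(IndexError):
        spliced_sequence(tx, g)


def test_spliced_length_matches_exon_sum(small_genome):
    genome, genes, _ = small_genome
    for gene in genes:
        for tx in gene.transcripts:
            assert len(spliced_sequence(tx, genome)) == sum(len(e) for e in tx.exons)
            if tx.is_coding:
                assert cds_sequence(tx, genome) in spliced_sequence(tx, genome)


def test_cds_sequence_spans_exons():
    g = GenomeSequence({"c": "TTATGAATTTAAATT"})
    tx = _tx([(2, 7), (9, 14)], cds=(2, 14))
    assert cds_sequence(tx, g) == "ATGAA" + "TAAAT"


def test_cds_sequence_noncoding_errors():
    g = GenomeSequence({"c": "ATGC"})
    tx = _tx([(0, 4)], biotype=Biotype.PROCESSED_TRANSCRIPT)
    with pytest.raises(ValueError, match="no CDS"):
        cds_sequence(tx, g)


def test_strand_symmetry_of_spliced_sequence(small_genome):
    """Reverse-complementing the chromosome and mirroring coordinates leaves
    the spliced sequence invariant."""
    genome, genes, _ = small_genome
    gene = genes[0]
    chrom = gene.chrom
    L = genome.length(chrom)
    rc_genome = GenomeSequence({chrom: reverse_complement(genome[chrom])})
    for tx in gene.transcripts:
        mirrored = TranscriptModel(
            transcript_id=tx.transcript_id,
            gene_id=tx.gene_id,
            chrom=chrom,
            strand="-" if tx.strand == "+" else "+",
            exons=tuple(
                sorted(
                    (ExonInterval(L - e.end, L - e.start) for e in tx.exons),
                    key=lambda e: e.start,
                )
            ),
            cds_start=None if not tx.is_coding else L - tx.cds_end,
            cds_end=None if not tx.is_coding else L - tx.cds_start,
            biotype=tx.biotype,
        )
        assert spliced_sequence(mirrored, rc_genome) == spliced_sequence(tx, genome)


# ---------------------------------------------------------------- translate
@pytest.mark.parametrize(
    "cds,protein",
    [
        ("ATGAAATAG", "MK*"),
        ("CAA", "Q"),
        ("ATGTAAATG", "M*"),  # stops at the first stop codon
        ("GGAGAA", "GE"),
    ],
)
def test_translate_examples(cds, protein):
    assert translate(cds) == protein


def test_translate_matches_biopython():
    import random

    rng = random.Random(0)
    for _ in range(50):
        n = rng.randrange(1, 30)
        seq = "".join(rng.choice("ACGT") for _ in range(3 * n))
        mine = translate(seq)
        bio = str(Seq(seq).translate())
        stop = bio.find("*")
        expected = bio if stop < 0 else bio[: stop + 1]
        assert mine == expected


def test_translate_partial_codon_warns():
    with pytest.warns(TranslationWarning):
        assert translate("ATGAA") == "M"


def test_translate_rejects_bad_codon_and_short_input():
    with pytest.raises(ValueError):
        translate("AT")
    with pytest.raises(ValueError):
        translate("ATGANA")


# ------------------------------------------------- positional classification
def test_map_first_cds_base_is_offset_one():
    tx = _tx([(100, 200)], cds=(130, 190))
    lab = map_genomic_position(tx, 130)
    assert lab.region is Region.CDS and lab.cds_offset == 1


def test_map_upstream_and_intergenic():
    tx = _tx([(1000, 1200)], cds=(1050, 1150))
    assert map_genomic_position(tx, 900).region is Region.UPSTREAM
    assert map_genomic_position(tx, 900).distance == 100
    assert map_genomic_position(tx, 1300).region is Region.DOWNSTREAM
    assert map_genomic_position(tx, 10000, flank=5000).region is Region.INTERGENIC


def test_map_intron_label_matches_published_style(fixtures):
    """19 bases past a donor whose last coding base is c.1716 -> c.1716+19."""
    fx = fixtures["chd7_like"]
    tx_short = fx["gene"].transcripts[1]
    lab = map_genomic_position(tx_short, 1984)
    assert lab.region is Region.INTRON
    assert lab.c == "1716+19"
    assert lab.intron_offset == 19


def test_map_partitions_every_position(fixtures):
    """Every position in the window maps to exactly one region label."""
    fx = fixtures["fig"]
    for tx in fx["gene"].transcripts:
        for pos in range(tx.start - 100, tx.end + 100):
            lab = map_genomic_position(tx, pos)
            assert lab.region in Region
            if lab.region is Region.CDS:
                assert 1 <= lab.cds_offset <= tx.cds_spliced_length


# ------------------------------------------------------------- invariants
def test_transcript_model_validation():
    with pytest.raises(ValueError, match="unsorted or overlapping"):
        _tx([(10, 20), (15, 30)])
    with pytest.raises(ValueError, match="outside exon union"):
        _tx([(10, 20)], cds=(5, 18))
    with pytest.raises(ValueError, match="strand"):
        _tx([(0, 10)], strand="x")
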