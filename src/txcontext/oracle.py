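"""Naive reference annotator used to validate the fast consequence caller.

This module re-derives every consequence from first principles and at full
price: it mutates the chromosome sequence itself, shifts every exon and CDS
coordinate through the edit, re-extracts the mutant transcript, re-translates
it, and compares proteins. Positional rules are evaluated on explicit sets of
genomic positions. Nothing here shares coordinate arithmetic with
:mod:`txcontext.consequence`; agreement between the two routes is the primary
correctness check of the annotation machinery, and the synthetic-data
generator also uses this route to verify planted expectations at generation
time.
"""

from __future__ import annotations

from .consequence import EffectTerm, ImpactClass, Variant, impact_of
from .gene_models import (
    CODON_TABLE,
    FLANK_WINDOW,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)

__all__ = ["oracle_consequence"]


def _naive_translate(seq: str) -> str:
    prot = ""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        prot += aa
        if aa == "*":
            break
    return prot


def _spliced(chrom_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    seq = ""
    for a, b in exons:
        if a < b:
            seq += chrom_seq[a:b]
    return reverse_complement(seq) if strand == "-" else seq


def _spliced_index(exons: list[tuple[int, int]], strand: str, pos: int) -> int | None:
    total = sum(b - a for a, b in exons if a < b)
    off = 0
    for a, b in exons:
        if a <= pos < b:
            i = off + (pos - a)
            return i if strand == "+" else total - 1 - i
        off += max(0, b - a)
    return None


def _genomic_at(exons: list[tuple[int, int]], strand: str, idx: int) -> int | None:
    """Inverse of :func:`_spliced_index`."""
    total = sum(b - a for a, b in exons if a < b)
    if not 0 <= idx < total:
        return None
    if strand == "-":
        idx = total - 1 - idx
    for a, b in exons:
        if idx < b - a:
            return a + idx
        idx -= b - a
    return None


def oracle_consequence(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    flank: int = FLANK_WINDOW,
) -> tuple[EffectTerm, ImpactClass]:
    """Brute-force effect term and impact class for one variant/transcript."""
    chrom_seq = genome[variant.chrom]
    p, ref, alt = variant.start0, variant.ref, variant.alt
    # positions actually changed: the shared anchor base of an indel is not;
    # a pure insertion is carried by its anchor base
    if (len(ref) > 1 or len(alt) > 1) and ref[0] == alt[0]:
        bases = set(range(p + 1, p + len(ref))) or {p}
    else:
        bases = set(range(p, p + len(ref)))
    tx = transcript

    # --- entirely outside the transcript ---------------------------------
    lo_b, hi_b = min(bases), max(bases)
    if hi_b < tx.start or lo_b >= tx.end:
        ref_pos = lo_b if tx.strand == "+" else hi_b
        if tx.strand == "+":
            upstream = ref_pos < tx.start
            dist = tx.start - ref_pos if upstream else ref_pos - tx.end + 1
        else:
            upstream = ref_pos >= tx.end
            dist = ref_pos - tx.end + 1 if upstream else tx.start - ref_pos
        if dist > flank:
            return _done(EffectTerm.INTERGENIC)
        return _done(EffectTerm.UPSTREAM if upstream else EffectTerm.DOWNSTREAM)

    # --- positional splice windows, as explicit base sets ----------------
    donor: set[int] = set()
    acceptor: set[int] = set()
    region: set[int] = set()
    if tx.is_coding:
        exlist = list(tx.exons)
        for left, right in zip(exlist, exlist[1:]):
            istart, iend = left.end, right.start
            left_coding = left.start < tx.cds_end and left.end > tx.cds_start
            right_coding = right.start < tx.cds_end and right.end > tx.cds_start
            if left_coding:
                two = set(range(istart, min(istart + 2, iend)))
                (donor if tx.strand == "+" else acceptor).update(two)
                region.update(range(istart + 2, min(istart + 8, iend)))
                region.update(range(max(left.start, left.end - 3), left.end))
            if right_coding:
                two = set(range(max(iend - 2, istart), iend))
                (acceptor if tx.strand == "+" else donor).update(two)
                region.update(range(max(iend - 8, istart), iend - 2))
                region.update(range(right.start, min(right.end, right.start + 3)))
    if bases & donor:
        return _done(EffectTerm.SPLICE_DONOR)
    if bases & acceptor:
        return _done(EffectTerm.SPLICE_ACCEPTOR)

    def is_exonic(pos: int) -> bool:
        return any(e.start <= pos < e.end for e in tx.exons)

    if not any(is_exonic(b_) for b_ in bases):
        if bases & region:
            return _done(EffectTerm.SPLICE_REGION)
        return _done(EffectTerm.INTRON)
    if not tx.is_coding:
        return _done(EffectTerm.NON_CODING_TRANSCRIPT)
    pure_insertion = len(ref) == 1 and len(alt) > 1 and ref[0] == alt[0]
    ins_slot = None
    if pure_insertion:
        a_idx = _spliced_index([(e.start, e.end) for e in tx.exons], tx.strand, p)
        if a_idx is not None:
            # inserted bases sit immediately before this spliced index
            ins_slot = a_idx + 1 if tx.strand == "+" else a_idx
    if not all(is_exonic(b_) for b_ in bases):
        # leaves an exon without touching a coding splice site: only happens
        # at junctions of UTR-only exons; treat as intronic disruption
        if bases & region:
            return _done(EffectTerm.SPLICE_REGION)
        return _done(EffectTerm.INTRON)

    # --- pure UTR --------------------------------------------------------
    exons_now = [(e.start, e.end) for e in tx.exons]
    cds_first = _spliced_index(
        exons_now, tx.strand, tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    )
    cds_len = tx.cds_spliced_length
    if ins_slot is not None:
        in_utr5 = ins_slot <= cds_first
        in_utr3 = ins_slot >= cds_first + cds_len
        coding_hit = not (in_utr5 or in_utr3)
    else:
        coding_hit = any(tx.cds_start <= b_ < tx.cds_end for b_ in bases)
        in_utr5 = all(
            _spliced_index(exons_now, tx.strand, b_) < cds_first for b_ in bases
        )
    if not coding_hit:
        if bases & region:
            return _done(EffectTerm.SPLICE_REGION)
        return _done(EffectTerm.UTR5 if in_utr5 else EffectTerm.UTR3)

    # --- CDS overlap: mutate the sequence and re-translate ----------------
    # (restricted to a window around the transcript; coordinates stay
    # absolute, only sequence extraction is done in the local frame)
    d = len(alt) - len(ref)

    def shift_endpoint(c: int) -> int:
        if c <= p:
            return c
        if c >= p + len(ref):
            return c + d
        return p + min(c - p, len(alt))

    exons0 = [(e.start, e.end) for e in tx.exons]
    exons1 = [(shift_endpoint(a), shift_endpoint(b)) for a, b in exons0]

    base0 = max(0, tx.start - 10)
    local = chrom_seq[base0 : min(len(chrom_seq), tx.end + 10)]
    pl = p - base0
    mut_local = local[:pl] + alt + local[pl + len(ref) :]
    ref_spliced = _spliced(local, [(a - base0, b - base0) for a, b in exons0], tx.strand)
    mut_spliced = _spliced(mut_local, [(a - base0, b - base0) for a, b in exons1], tx.strand)

    start_base = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    t0 = _spliced_index(exons0, tx.strand, start_base)
    if tx.strand == "+":
        cs1 = shift_endpoint(tx.cds_start)
        # a start base snapped into the alt allele must point at a base
        m0 = _spliced_index(exons1, tx.strand, min(cs1, len(chrom_seq) + d - 1))
    else:
        ce1 = shift_endpoint(tx.cds_end)
        m0 = _spliced_index(exons1, tx.strand, max(ce1 - 1, 0))
    if m0 is None:
        m0 = t0  # degenerate snap; fall back to the reference start offset

    p_ref = _naive_translate(ref_spliced[t0:])
    p_alt = _naive_translate(mut_spliced[m0:])

    start_codon_bases = {
        _genomic_at(exons0, tx.strand, t0 + i) for i in range(3)
    } - {None}
    ref_stop = p_ref.index("*") if "*" in p_ref else None
    stop_codon_bases = set()
    if ref_stop is not None:
        stop_codon_bases = {
            _genomic_at(exons0, tx.strand, t0 + 3 * ref_stop + i) for i in range(3)
        } - {None}

    # classification by direct comparison, most severe applicable first
    if ins_slot is not None:
        start_hit = t0 < ins_slot < t0 + 3
        stop_hit = ref_stop is not None and (
            t0 + 3 * ref_stop < ins_slot < t0 + 3 * ref_stop + 3
        )
    else:
        start_hit = bool(bases & start_codon_bases)
        stop_hit = bool(bases & stop_codon_bases)
    if start_hit and mut_spliced[m0 : m0 + 3] != "ATG":
        return _done(EffectTerm.START_LOST)
    if d % 3 != 0:
        return _done(EffectTerm.FRAMESHIFT)
    if p_alt == p_ref:
        term = EffectTerm.STOP_RETAINED if stop_hit else EffectTerm.SYNONYMOUS
        return _region_or(term, bases, region)
    alt_stop = p_alt.index("*") if "*" in p_alt else None
    if ref_stop is not None:
        expect = ref_stop + d // 3
        if alt_stop is None or alt_stop > expect:
            return _done(EffectTerm.STOP_LOST)
        if alt_stop < expect:
            return _done(EffectTerm.STOP_GAINED)
    elif alt_stop is not None:
        return _done(EffectTerm.STOP_GAINED)
    if d > 0:
        return _done(EffectTerm.INFRAME_INSERTION)
    if d < 0:
        return _done(EffectTerm.INFRAME_DELETION)
    return _done(EffectTerm.MISSENSE)


def _region_or(
    term: EffectTerm, bases: set[int], region: set[int]
) -> tuple[EffectTerm, ImpactClass]:
    if bases & region:
        return _done(EffectTerm.SPLICE_REGION)
    return _done(term)


def _done(term: EffectTerm) -> tuple[EffectTerm, ImpactClass]:
    return term, impact_of(term)
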