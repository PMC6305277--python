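"""Per-transcript variant consequence calling and impact-class assignment.

The same genomic change is annotated independently against every transcript
of a gene; divergence of the resulting impact classes across transcripts is
what the downstream cohort analysis measures. Coding effects are determined
by rebuilding the mutant spliced transcript, re-translating, and comparing
the two proteins; positional effects (splice sites, UTRs, introns, flanks)
by fixed windows.

Severity conventions
--------------------
* splice site = the 2 intronic bases on either side of a junction flanking a
  coding exon (HIGH);
* splice region = intronic bases 3–8 or exonic bases 1–3 from such a
  junction (LOW), reported only when no more severe coding term applies;
* within the CDS, a disrupted start codon is reported as ``start_lost`` even
  when the substitution also creates a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .gene_models import (
    AA3,
    CODON_TABLE,
    FLANK_WINDOW,
    Biotype,
    GeneModel,
    GenomeSequence,
    PositionLabel,
    Region,
    TranscriptModel,
    map_genomic_position,
    reverse_complement,
    spliced_sequence,
)

__all__ = [
    "ConsequenceCall",
    "EffectTerm",
    "ImpactClass",
    "Variant",
    "annotate_gene",
    "consequence_for_transcript",
    "impact_of",
    "normalize",
    "read_vcf",
    "write_annotated_tsv",
    "write_annotated_vcf",
]


class EffectTerm(str, Enum):
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    FRAMESHIFT = "frameshift_variant"
    SPLICE_ACCEPTOR = "splice_acceptor_variant"
    SPLICE_DONOR = "splice_donor_variant"
    MISSENSE = "missense_variant"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    SYNONYMOUS = "synonymous_variant"
    STOP_RETAINED = "stop_retained_variant"
    SPLICE_REGION = "splice_region_variant"
    INTRON = "intron_variant"
    UTR5 = "five_prime_utr_variant"
    UTR3 = "three_prime_utr_variant"
    UPSTREAM = "upstream_variant"
    DOWNSTREAM = "downstream_variant"
    NON_CODING_TRANSCRIPT = "non_coding_transcript_variant"
    INTERGENIC = "intergenic_variant"


class ImpactClass(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"

    @property
    def rank(self) -> int:
        return {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}[self.value]

    def __lt__(self, other: "ImpactClass") -> bool:  # type: ignore[override]
        return self.rank < other.rank


_IMPACT_TABLE: dict[EffectTerm, ImpactClass] = {
    EffectTerm.STOP_GAINED: ImpactClass.HIGH,
    EffectTerm.STOP_LOST: ImpactClass.HIGH,
    EffectTerm.START_LOST: ImpactClass.HIGH,
    EffectTerm.FRAMESHIFT: ImpactClass.HIGH,
    EffectTerm.SPLICE_ACCEPTOR: ImpactClass.HIGH,
    EffectTerm.SPLICE_DONOR: ImpactClass.HIGH,
    EffectTerm.MISSENSE: ImpactClass.MODERATE,
    EffectTerm.INFRAME_INSERTION: ImpactClass.MODERATE,
    EffectTerm.INFRAME_DELETION: ImpactClass.MODERATE,
    EffectTerm.SYNONYMOUS: ImpactClass.LOW,
    EffectTerm.STOP_RETAINED: ImpactClass.LOW,
    EffectTerm.SPLICE_REGION: ImpactClass.LOW,
}

#: most-severe-first ordering used to resolve competing applicable terms
SEVERITY_ORDER: tuple[EffectTerm, ...] = (
    EffectTerm.SPLICE_ACCEPTOR,
    EffectTerm.SPLICE_DONOR,
    EffectTerm.STOP_GAINED,
    EffectTerm.FRAMESHIFT,
    EffectTerm.STOP_LOST,
    EffectTerm.START_LOST,
    EffectTerm.INFRAME_INSERTION,
    EffectTerm.INFRAME_DELETION,
    EffectTerm.MISSENSE,
    EffectTerm.SPLICE_REGION,
    EffectTerm.SYNONYMOUS,
    EffectTerm.STOP_RETAINED,
    EffectTerm.UTR5,
    EffectTerm.UTR3,
    EffectTerm.NON_CODING_TRANSCRIPT,
    EffectTerm.INTRON,
    EffectTerm.UPSTREAM,
    EffectTerm.DOWNSTREAM,
    EffectTerm.INTERGENIC,
)
_SEVERITY_RANK = {t: i for i, t in enumerate(SEVERITY_ORDER)}


def impact_of(effect: EffectTerm) -> ImpactClass:
    """Four-level impact of an effect term.

    HIGH covers alterations to coding length or frame (and the splice sites
    that imply them), MODERATE missense-like protein changes, LOW silent and
    splice-region changes, MODIFIER everything non-coding.
    """
    return _IMPACT_TABLE.get(effect, ImpactClass.MODIFIER)


def most_severe(terms: Iterable[EffectTerm]) -> EffectTerm:
    return min(terms, key=_SEVERITY_RANK.__getitem__)


_CODING_EFFECTS = frozenset(
    {
        EffectTerm.STOP_GAINED,
        EffectTerm.STOP_LOST,
        EffectTerm.START_LOST,
        EffectTerm.FRAMESHIFT,
        EffectTerm.MISSENSE,
        EffectTerm.INFRAME_INSERTION,
        EffectTerm.INFRAME_DELETION,
        EffectTerm.SYNONYMOUS,
        EffectTerm.STOP_RETAINED,
    }
)


@dataclass(frozen=True)
class Variant:
    """A biallelic genomic change, VCF-style: ``pos`` is 1-based and the ref
    allele is anchored (non-empty)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty (anchored alleles)")
        for allele in (self.ref, self.alt):
            if set(allele) - set("ACGT"):
                raise ValueError(f"allele {allele!r} not over ACGT")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def start0(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:g.{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ConsequenceCall:
    """The effect of one variant on one transcript."""

    transcript_id: str
    effect: EffectTerm
    impact: ImpactClass
    cdna_label: str
    protein_label: str | None = None
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(variant: Variant, genome: GenomeSequence) -> Variant:
    """Trim shared context and left-align indels against the reference.

    Idempotent; raises if the declared ref allele does not match the genome.
    """
    chrom_seq = genome[variant.chrom]
    observed = chrom_seq[variant.start0 : variant.end0]
    if observed != variant.ref:
        raise ValueError(
            f"ref mismatch at {variant.chrom}:{variant.pos}: variant says "
            f"{variant.ref!r}, genome has {observed!r}"
        )
    pos0, ref, alt = variant.start0, variant.ref, variant.alt
    changed = True
    while changed:
        changed = False
        # shared terminal base: truncate
        while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                break
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # pure indel ending in the same base: roll left
        while (
            len(ref) != len(alt)
            and ref
            and alt
            and ref[-1] == alt[-1]
            and pos0 > 0
        ):
            prev = chrom_seq[pos0 - 1]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos0 -= 1
            changed = True
    # shared leading context beyond the single anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos0 = ref[1:], alt[1:], pos0 + 1
    return Variant(chrom=variant.chrom, pos=pos0 + 1, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# coding-effect classification
# ---------------------------------------------------------------------------

def _translate_open(seq: str, start: int) -> str:
    """Translate from ``start`` until the first stop codon or sequence end."""
    out = []
    for i in range(start, len(seq) - 2, 3):
        aa = CODON_TABLE.get(seq[i : i + 3])
        if aa is None:
            raise ValueError(f"untranslatable codon {seq[i:i + 3]!r}")
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


def _classify_coding(
    p_ref: str,
    p_alt: str,
    len_ref: int,
    len_alt: int,
    overlaps_start: bool,
    start_intact: bool,
    overlaps_stop: bool,
) -> EffectTerm:
    """Decide the coding effect term from the two translated proteins.

    Shared decision order (mirrored, independently, by the naive oracle):
    start disruption, then frame, then protein identity, then stop position
    relative to its in-frame expectation, then inframe/missense.
    """
    if overlaps_start and not start_intact:
        return EffectTerm.START_LOST
    d = len_alt - len_ref
    if d % 3 != 0:
        return EffectTerm.FRAMESHIFT
    if p_alt == p_ref:
        return EffectTerm.STOP_RETAINED if overlaps_stop else EffectTerm.SYNONYMOUS
    ref_stop = p_ref.index("*") if "*" in p_ref else None
    alt_stop = p_alt.index("*") if "*" in p_alt else None
    if ref_stop is not None:
        expected = ref_stop + d // 3
        if alt_stop is None or alt_stop > expected:
            return EffectTerm.STOP_LOST
        if alt_stop < expected:
            return EffectTerm.STOP_GAINED
    elif alt_stop is not None:
        return EffectTerm.STOP_GAINED
    if d > 0:
        return EffectTerm.INFRAME_INSERTION
    if d < 0:
        return EffectTerm.INFRAME_DELETION
    return EffectTerm.MISSENSE


def _first_diff(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def _protein_label(
    effect: EffectTerm, p_ref: str, p_alt: str, codon_idx: int
) -> str | None:
    """Compact HGVS-style protein label (not full HGVS edge-case compliance)."""
    if effect not in _CODING_EFFECTS:
        return None
    if effect is EffectTerm.START_LOST:
        return "p.Met1?"
    if effect is EffectTerm.SYNONYMOUS:
        aa = p_ref[codon_idx] if codon_idx < len(p_ref) else p_ref[-1]
        return f"p.{AA3[aa]}{codon_idx + 1}="
    if effect is EffectTerm.STOP_RETAINED:
        stop = p_ref.index("*") if "*" in p_ref else len(p_ref) - 1
        return f"p.*{stop + 1}="
    i = _first_diff(p_ref, p_alt)
    ref_aa = p_ref[i] if i < len(p_ref) else "*"
    alt_aa = p_alt[i] if i < len(p_alt) else "*"
    if effect is EffectTerm.STOP_GAINED:
        return f"p.{AA3[ref_aa]}{i + 1}*"
    if effect is EffectTerm.STOP_LOST:
        stop = p_ref.index("*") if "*" in p_ref else len(p_ref) - 1
        return f"p.*{stop + 1}{AA3.get(alt_aa, alt_aa)}ext"
    if effect is EffectTerm.MISSENSE:
        return f"p.{AA3[ref_aa]}{i + 1}{AA3[alt_aa]}"
    if effect is EffectTerm.FRAMESHIFT:
        return f"p.{AA3[ref_aa]}{i + 1}fs"
    if effect is EffectTerm.INFRAME_DELETION:
        return f"p.{AA3[ref_aa]}{i + 1}del"
    if effect is EffectTerm.INFRAME_INSERTION:
        return f"p.{AA3[ref_aa]}{i + 1}ins"
    return None


# ---------------------------------------------------------------------------
# positional machinery
# ---------------------------------------------------------------------------

def _splice_hits(
    transcript: TranscriptModel, span: tuple[int, int]
) -> tuple[EffectTerm | None, bool]:
    """Check the variant span against splice windows of every junction.

    Returns ``(site_term, region_hit)``: ``site_term`` is the most severe
    splice_donor/splice_acceptor hit (2 intronic bases), ``region_hit``
    flags intronic 3–8 / exonic 1–3 proximity. Only junctions flanking a
    CDS-overlapping exon count.
    """
    if not transcript.is_coding:
        return None, False
    lo, hi = span

    def overlaps(a: int, b: int) -> bool:
        return lo < b and hi > a

    site: EffectTerm | None = None
    region = False
    exons = transcript.exons
    for left, right in zip(exons, exons[1:]):
        intron = (left.end, right.start)
        for exon, at_exon_end in ((left, True), (right, False)):
            coding_exon = (
                exon.start < transcript.cds_end and exon.end > transcript.cds_start
            )
            if not coding_exon:
                continue
            if at_exon_end:
                site_ivl = (intron[0], min(intron[0] + 2, intron[1]))
                region_ivl = (intron[0] + 2, min(intron[0] + 8, intron[1]))
                exonic_ivl = (max(exon.start, exon.end - 3), exon.end)
                donor_side = transcript.strand == "+"
            else:
                site_ivl = (max(intron[1] - 2, intron[0]), intron[1])
                region_ivl = (max(intron[1] - 8, intron[0]), intron[1] - 2)
                exonic_ivl = (exon.start, min(exon.end, exon.start + 3))
                donor_side = transcript.strand == "-"
            if overlaps(*site_ivl):
                term = (
                    EffectTerm.SPLICE_DONOR if donor_side else EffectTerm.SPLICE_ACCEPTOR
                )
                if site is None or _SEVERITY_RANK[term] < _SEVERITY_RANK[site]:
                    site = term
            if overlaps(*region_ivl) or overlaps(*exonic_ivl):
                region = True
    return site, region


def _edit(variant: Variant) -> tuple[int, int, str, tuple[int, int]]:
    """Minimal edit of a normalized variant.

    Returns ``(edit0, edit1, edit_alt, pos_span)``: the genomic span whose
    bases are actually replaced (the shared anchor base of an indel is not),
    the replacement sequence, and the span used for positional rules (for a
    pure insertion, the anchor base carries the insertion point).
    """
    if (len(variant.ref) > 1 or len(variant.alt) > 1) and variant.ref[0] == variant.alt[0]:
        e0, e1, ealt = variant.start0 + 1, variant.end0, variant.alt[1:]
        if e0 == e1:  # pure insertion
            return e0, e1, ealt, (variant.start0, variant.start0 + 1)
        return e0, e1, ealt, (e0, e1)
    return variant.start0, variant.end0, variant.alt, (variant.start0, variant.end0)


def _edit_spliced(
    transcript: TranscriptModel, edit0: int, edit1: int, edit_alt: str
) -> tuple[int, int, str] | None:
    """Spliced-coordinate edit span and transcript-orientation replacement,
    or ``None`` when the edited bases are not fully exonic (or, for a pure
    insertion, when the anchor base is not exonic)."""
    if edit0 == edit1:  # pure insertion anchored at edit0 - 1
        anchor_idx = transcript.genomic_to_spliced(edit0 - 1)
        if anchor_idx is None:
            return None
        slot = anchor_idx + 1 if transcript.strand == "+" else anchor_idx
        alt = reverse_complement(edit_alt) if transcript.strand == "-" else edit_alt
        return slot, slot, alt
    idxs = [transcript.genomic_to_spliced(p) for p in range(edit0, edit1)]
    if any(i is None for i in idxs):
        return None
    s0, s1 = min(idxs), max(idxs) + 1
    alt = reverse_complement(edit_alt) if transcript.strand == "-" else edit_alt
    return s0, s1, alt


def _cdna_change_suffix(transcript: TranscriptModel, variant: Variant) -> str:
    ref, alt = variant.ref, variant.alt
    if transcript.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if len(ref) == 1 and len(alt) == 1:
        return f"{ref}>{alt}"
    if len(ref) > len(alt) == 1 and ref[0] == alt[0]:
        return f"del{ref[1:]}"
    if len(alt) > len(ref) == 1 and ref[0] == alt[0]:
        return f"ins{alt[1:]}"
    return f"delins{alt}"


def _cdna_label(
    transcript: TranscriptModel, variant: Variant, label: PositionLabel
) -> str:
    suffix = _cdna_change_suffix(transcript, variant)
    if label.region in (Region.UPSTREAM, Region.DOWNSTREAM, Region.INTERGENIC):
        return f"g.{variant.pos}{variant.ref}>{variant.alt}" if variant.is_snv else (
            f"g.{variant.pos}{suffix}"
        )
    prefix = "n." if label.region is Region.NONCODING_EXON else "c."
    return f"{prefix}{label.c}{suffix}"


# ---------------------------------------------------------------------------
# the decision tree
# ---------------------------------------------------------------------------

def consequence_for_transcript(
    variant: Variant,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    flank: int = FLANK_WINDOW,
) -> ConsequenceCall:
    """Classify one (normalized) variant against one transcript."""
    if variant.end0 > genome.length(variant.chrom):
        raise IndexError(
            f"variant {variant} overlaps the end of chromosome {variant.chrom}"
        )
    if variant.chrom != transcript.chrom:
        raise ValueError(
            f"variant on {variant.chrom} vs transcript on {transcript.chrom}"
        )
    edit0, edit1, edit_alt, span = _edit(variant)

    # transcript-orientation anchor position for the positional label: use
    # the transcription-wise first affected base
    anchor = span[0] if transcript.strand == "+" else span[1] - 1
    pos_label = map_genomic_position(transcript, anchor, flank=flank)

    # (1) entirely outside the transcript
    if span[1] <= transcript.start or span[0] >= transcript.end:
        term = {
            Region.UPSTREAM: EffectTerm.UPSTREAM,
            Region.DOWNSTREAM: EffectTerm.DOWNSTREAM,
            Region.INTERGENIC: EffectTerm.INTERGENIC,
        }[pos_label.region]
        return _call(transcript, variant, term, pos_label)

    # (2)/(3) splice windows
    site_term, region_hit = _splice_hits(transcript, span)
    if site_term is not None:
        return _call(transcript, variant, site_term, pos_label)

    spliced_span = _edit_spliced(transcript, edit0, edit1, edit_alt)

    if spliced_span is None:
        # fully or partially intronic (junction-crossers at coding exons were
        # caught above because any span leaving an exon covers intron bases
        # 1-2; remaining cases are intronic or cross UTR-exon junctions)
        if not transcript.is_coding:
            exonic_hit = any(
                transcript.genomic_to_spliced(p) is not None
                for p in range(span[0], span[1])
            )
            term = (
                EffectTerm.NON_CODING_TRANSCRIPT if exonic_hit else EffectTerm.INTRON
            )
        else:
            term = EffectTerm.SPLICE_REGION if region_hit else EffectTerm.INTRON
        return _call(transcript, variant, term, pos_label)

    # (4) exonic in a non-coding transcript
    if not transcript.is_coding:
        return _call(transcript, variant, EffectTerm.NON_CODING_TRANSCRIPT, pos_label)

    s0, s1, alt_t = spliced_span
    cds_lo, cds_hi = transcript.cds_spliced_interval

    # (5) pure UTR spans
    if s1 <= cds_lo or s0 >= cds_hi:
        base = EffectTerm.UTR5 if s1 <= cds_lo else EffectTerm.UTR3
        term = EffectTerm.SPLICE_REGION if region_hit else base
        return _call(transcript, variant, term, pos_label)

    # (6) CDS-overlapping: rebuild, re-translate, compare
    ref_spliced = spliced_sequence(transcript, genome)
    mut_spliced = ref_spliced[:s0] + alt_t + ref_spliced[s1:]
    d_len = len(alt_t) - (s1 - s0)
    if cds_lo <= s0:
        mut_lo = cds_lo
    elif cds_lo >= s1:
        mut_lo = cds_lo + d_len
    else:
        mut_lo = s0 + min(cds_lo - s0, len(alt_t))
    p_ref = _translate_open(ref_spliced, cds_lo)
    p_alt = _translate_open(mut_spliced, mut_lo)
    ref_stop = p_ref.index("*") if "*" in p_ref else None
    overlaps_start = s0 < cds_lo + 3 and s1 > cds_lo
    overlaps_stop = ref_stop is not None and (
        s0 < cds_lo + 3 * ref_stop + 3 and s1 > cds_lo + 3 * ref_stop
    )
    start_intact = mut_spliced[mut_lo : mut_lo + 3] == "ATG"
    coding_term = _classify_coding(
        p_ref, p_alt, s1 - s0, len(alt_t), overlaps_start, start_intact, overlaps_stop
    )
    term = coding_term
    if region_hit and _SEVERITY_RANK[EffectTerm.SPLICE_REGION] < _SEVERITY_RANK[term]:
        term = EffectTerm.SPLICE_REGION
    codon_idx = (s0 - cds_lo) // 3
    protein = _protein_label(coding_term, p_ref, p_alt, codon_idx)
    low_conf = not transcript.cds_frame_complete or not ref_spliced[
        cds_lo : cds_lo + 3
    ] == "ATG"
    call = _call(transcript, variant, term, pos_label, low_confidence=low_conf)
    if term in _CODING_EFFECTS or (term is EffectTerm.SPLICE_REGION and protein):
        call = replace(call, protein_label=protein if term in _CODING_EFFECTS else None)
    return call


def _call(
    transcript: TranscriptModel,
    variant: Variant,
    term: EffectTerm,
    pos_label: PositionLabel,
    low_confidence: bool = False,
) -> ConsequenceCall:
    return ConsequenceCall(
        transcript_id=transcript.transcript_id,
        effect=term,
        impact=impact_of(term),
        cdna_label=_cdna_label(transcript, variant, pos_label),
        protein_label=None,
        low_confidence=low_confidence,
    )


def annotate_gene(
    variant: Variant,
    gene: GeneModel,
    genome: GenomeSequence,
    biotype_whitelist: frozenset[Biotype] | set[Biotype],
    flank: int = FLANK_WINDOW,
) -> list[ConsequenceCall]:
    """One call per whitelisted transcript, ordered by transcript_id."""
    if not biotype_whitelist:
        raise ValueError("empty biotype whitelist")
    calls = []
    for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        if tx.biotype in biotype_whitelist:
            calls.append(consequence_for_transcript(variant, tx, genome, flank=flank))
    return calls


# ---------------------------------------------------------------------------
# VCF / TSV I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[Variant]:
    """Read site records from a VCF (v4.x); multi-allelic records are split
    into biallelic variants."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt))
    return out


def write_annotated_tsv(
    rows: Iterable[tuple[Variant, str, ConsequenceCall]], path: str | Path
) -> None:
    """Flat per-(variant, transcript) annotation table."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene_id\ttranscript_id\teffect\timpact\t"
            "cdna_label\tprotein_label\tlow_confidence\n"
        )
        for variant, gene_id, call in rows:
            fh.write(
                "\t".join(
                    [
                        variant.chrom,
                        str(variant.pos),
                        variant.ref,
                        variant.alt,
                        gene_id,
                        call.transcript_id,
                        call.effect.value,
                        call.impact.value,
                        call.cdna_label,
                        call.protein_label or ".",
                        "1" if call.low_confidence else "0",
                    ]
                )
                + "\n"
            )


def write_annotated_vcf(
    annotations: Sequence[tuple[Variant, Sequence[ConsequenceCall]]],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Site-only VCF with per-transcript annotations in the ``TXC`` INFO tag
    (``transcript|effect|impact|cdna|protein``, comma-delimited)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=TXC,Number=.,Type=String,Description="Transcript '
            'consequence: transcript|effect|impact|cdna|protein">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for variant, calls in annotations:
            txc = ",".join(
                "|".join(
                    [
                        c.transcript_id,
                        c.effect.value,
                        c.impact.value,
                        c.cdna_label,
                        c.protein_label or ".",
                    ]
                )
                for c in calls
            )
            info = f"TXC={txc}" if txc else "."
            fh.write(
                f"{variant.chrom}\t{variant.pos}\t.\t{variant.ref}\t"
                f"{variant.alt}\t.\t.\t{info}\n"
            )
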