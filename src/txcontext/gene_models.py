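"""Genome and transcript-model data structures, file I/O, and coordinate maps.

Internal coordinates are 0-based half-open throughout; the GTF reader/writer
converts to and from the 1-based inclusive convention at the boundary, and the
VCF layer (see :mod:`txcontext.consequence`) converts 1-based positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "Biotype",
    "ExonInterval",
    "GeneModel",
    "GenomeSequence",
    "ParseError",
    "PositionLabel",
    "Region",
    "TranscriptModel",
    "TranslationWarning",
    "cds_sequence",
    "map_genomic_position",
    "read_fasta",
    "read_gtf",
    "reverse_complement",
    "spliced_sequence",
    "translate",
    "write_fasta",
    "write_gtf",
]

#: bases considered valid in genome sequences
VALID_BASES = frozenset("ACGTN")

#: distance (bp) on either side of a transcript still reported as
#: upstream/downstream rather than intergenic
FLANK_WINDOW = 5000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_STOPS = ("TAA", "TAG", "TGA")

# standard nuclear codon table, stops as '*'
CODON_TABLE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            CODON_TABLE[_a + _b + _c] = _AAS[_i * 16 + _j * 4 + _k]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class TranslationWarning(UserWarning):
    """Emitted when a trailing partial codon is discarded during translation."""


class Biotype(str, Enum):
    """Transcript functional category.

    The analysis retains the four categories whose variants can plausibly
    change protein-coding potential between isoforms; everything else maps
    to ``OTHER`` and is removed by the biotype filter.
    """

    PROTEIN_CODING = "protein_coding"
    NMD = "nonsense_mediated_decay"
    RETAINED_INTRON = "retained_intron"
    PROCESSED_TRANSCRIPT = "processed_transcript"
    OTHER = "other"

    @classmethod
    def from_string(cls, text: str) -> "Biotype":
        try:
            return cls(text)
        except ValueError:
            return cls.OTHER


#: the default whitelist used by the cohort analysis
DEFAULT_BIOTYPE_WHITELIST = frozenset(
    {
        Biotype.PROTEIN_CODING,
        Biotype.NMD,
        Biotype.RETAINED_INTRON,
        Biotype.PROCESSED_TRANSCRIPT,
    }
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonInterval:
    """A genomic interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


class GenomeSequence:
    """Chromosome name → uppercase nucleotide string."""

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("no records")
        clean: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"invalid bases {sorted(bad)} in chromosome {name!r}"
                )
            clean[name] = seq
        self.chromosomes: dict[str, str] = clean

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; out-of-bounds lookups are errors."""
        seq = self[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise IndexError(
                f"interval [{start}, {end}) outside chromosome {chrom!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """One transcript: exon structure, optional CDS bounds, strand, biotype.

    ``cds_start``/``cds_end`` are genomic (0-based half-open) bounds of the
    CDS union including the stop codon; ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: Biotype = Biotype.PROTEIN_CODING

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if not a.end <= b.start:
                raise ValueError(
                    f"exons of {self.transcript_id} unsorted or overlapping: "
                    f"[{a.start},{a.end}) vs [{b.start},{b.end})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not self.cds_start < self.cds_end:
                raise ValueError("empty CDS interval")
            if not (
                any(self.cds_start in e for e in self.exons)
                and any(self.cds_end - 1 in e for e in self.exons)
            ):
                raise ValueError(
                    f"CDS bounds of {self.transcript_id} outside exon union"
                )
            if self.cds_spliced_length < 3:
                raise ValueError(
                    f"spliced CDS of {self.transcript_id} shorter than one codon"
                )

    # ------------------------------------------------------------------ span
    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_spliced_length(self) -> int:
        if not self.is_coding:
            return 0
        return sum(
            min(e.end, self.cds_end) - max(e.start, self.cds_start)
            for e in self.exons
            if e.start < self.cds_end and e.end > self.cds_start
        )

    @property
    def cds_frame_complete(self) -> bool:
        """True when the spliced CDS length is a whole number of codons."""
        return self.is_coding and self.cds_spliced_length % 3 == 0

    # ------------------------------------------------------- coordinate maps
    def genomic_to_spliced(self, pos: int) -> int | None:
        """Spliced (transcription-order) index of a genomic position.

        Returns ``None`` for intronic or out-of-transcript positions.
        """
        offset = 0
        for e in self.exons:
            if pos in e:
                plus_offset = offset + (pos - e.start)
                if self.strand == "+":
                    return plus_offset
                return self.spliced_length - 1 - plus_offset
            offset += len(e)
        return None

    def spliced_to_genomic(self, idx: int) -> int:
        if not 0 <= idx < self.spliced_length:
            raise IndexError(f"spliced index {idx} out of range")
        if self.strand == "-":
            idx = self.spliced_length - 1 - idx
        for e in self.exons:
            if idx < len(e):
                return e.start + idx
            idx -= len(e)
        raise AssertionError("unreachable")

    @property
    def cds_spliced_interval(self) -> tuple[int, int]:
        """CDS bounds as a half-open interval in spliced coordinates."""
        if not self.is_coding:
            raise ValueError(f"transcript {self.transcript_id} has no CDS")
        if self.strand == "+":
            lo = self.genomic_to_spliced(self.cds_start)
            hi = self.genomic_to_spliced(self.cds_end - 1)
        else:
            lo = self.genomic_to_spliced(self.cds_end - 1)
            hi = self.genomic_to_spliced(self.cds_start)
        assert lo is not None and hi is not None
        return lo, hi + 1

    def exons_transcription_order(self) -> tuple[ExonInterval, ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class GeneModel:
    """A gene: one or more transcript models sharing a locus."""

    gene_id: str
    symbol: str
    transcripts: tuple[TranscriptModel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.transcripts = tuple(self.transcripts)
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} spans chromosomes {chroms}")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"transcript gene_id mismatch in {self.gene_id}")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate transcript ids in gene {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`."""
    path = Path(path)
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ParseError(f"{path}: duplicate record {rec.id!r}")
            records[rec.id] = str(rec.seq)
    except ValueError as exc:  # Biopython signals malformed input this way
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no records")
    try:
        return GenomeSequence(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome.chromosomes[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_REQUIRED = ("gene_id", "transcript_id")


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, raw = chunk.partition(" ")
        attrs[key] = raw.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file (1-based inclusive coordinates).

    Transcript structure is assembled from ``exon`` features grouped by
    ``transcript_id``; CDS bounds are the union of ``CDS`` features. Unknown
    ``transcript_biotype`` strings map to :attr:`Biotype.OTHER`.
    """
    path = Path(path)
    exons: dict[str, list[ExonInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    gene_symbol: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if ftype == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}: line {lineno}: missing gene_id")
                if gid not in gene_symbol:
                    gene_order.append(gid)
                gene_symbol[gid] = attrs.get("gene_name", gid)
                continue
            if ftype not in ("transcript", "exon", "CDS"):
                continue
            for key in _GTF_REQUIRED:
                if key not in attrs:
                    raise ParseError(
                        f"{path}: line {lineno}: missing attribute {key!r}"
                    )
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            if gid not in gene_symbol:
                gene_order.append(gid)
                gene_symbol[gid] = attrs.get("gene_name", gid)
            info = meta.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": Biotype.OTHER,
                    "span": None,
                },
            )
            if info["gene_id"] != gid or info["chrom"] != chrom:
                raise ParseError(
                    f"{path}: line {lineno}: transcript {tid} attached to "
                    "conflicting gene or chromosome"
                )
            if "transcript_biotype" in attrs:
                info["biotype"] = Biotype.from_string(attrs["transcript_biotype"])
            if ftype == "transcript":
                info["span"] = (start1 - 1, end1)
            elif ftype == "exon":
                exons.setdefault(tid, []).append(ExonInterval(start1 - 1, end1))
            else:  # CDS
                cds.setdefault(tid, []).append((start1 - 1, end1))

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, info in meta.items():
        if tid not in exons:
            raise ParseError(f"{path}: transcript {tid} has no exon features")
        ex = tuple(sorted(exons[tid], key=lambda e: e.start))
        span = info["span"]
        if span is not None and (ex[0].start < span[0] or ex[-1].end > span[1]):
            raise ParseError(
                f"{path}: exon of {tid} outside declared transcript range"
            )
        cs = ce = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=ex,
                cds_start=cs,
                cds_end=ce,
                biotype=info["biotype"],
            )
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid}: {exc}") from exc
        genes.setdefault(info["gene_id"], []).append(model)

    out = []
    for gid in gene_order:
        if gid not in genes:
            continue
        txs = tuple(sorted(genes[gid], key=lambda t: t.transcript_id))
        out.append(GeneModel(gene_id=gid, symbol=gene_symbol.get(gid, gid), transcripts=txs))
    # genes never named on a gene line still need to be emitted
    for gid in genes:
        if gid not in gene_symbol:
            txs = tuple(sorted(genes[gid], key=lambda t: t.transcript_id))
            out.append(GeneModel(gene_id=gid, symbol=gid, transcripts=txs))
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive), round-trippable by
    :func:`read_gtf`."""

    def attrs(gene: GeneModel, tx: TranscriptModel | None = None) -> str:
        parts = [f'gene_id "{gene.gene_id}"', f'gene_name "{gene.symbol}"']
        if tx is not None:
            parts.append(f'transcript_id "{tx.transcript_id}"')
            parts.append(f'transcript_biotype "{tx.biotype.value}"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for gene in genes:
            fh.write(
                "\t".join(
                    [
                        gene.chrom, "txcontext", "gene",
                        str(gene.start + 1), str(gene.end), ".",
                        gene.transcripts[0].strand, ".", attrs(gene),
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom, "txcontext", "transcript",
                            str(tx.start + 1), str(tx.end), ".",
                            tx.strand, ".", attrs(gene, tx),
                        ]
                    )
                    + "\n"
                )
                for e in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom, "txcontext", "exon",
                                str(e.start + 1), str(e.end), ".",
                                tx.strand, ".", attrs(gene, tx),
                            ]
                        )
                        + "\n"
                    )
                if tx.is_coding:
                    for e in tx.exons:
                        lo = max(e.start, tx.cds_start)
                        hi = min(e.end, tx.cds_end)
                        if lo < hi:
                            fh.write(
                                "\t".join(
                                    [
                                        gene.chrom, "txcontext", "CDS",
                                        str(lo + 1), str(hi), ".",
                                        tx.strand, "0", attrs(gene, tx),
                                    ]
                                )
                                + "\n"
                            )


# ---------------------------------------------------------------------------
# sequence extraction and translation
# ---------------------------------------------------------------------------

def spliced_sequence(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Exon sequences concatenated in transcription order."""
    chrom_len = genome.length(transcript.chrom)
    if transcript.end > chrom_len or transcript.start < 0:
        raise IndexError(
            f"transcript {transcript.transcript_id} extends beyond chromosome "
            f"{transcript.chrom} of length {chrom_len}"
        )
    seq = "".join(
        genome.fetch(transcript.chrom, e.start, e.end) for e in transcript.exons
    )
    return reverse_complement(seq) if transcript.strand == "-" else seq


def cds_sequence(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced sequence restricted to the CDS, in translation orientation."""
    if not transcript.is_coding:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    lo, hi = transcript.cds_spliced_interval
    return spliced_sequence(transcript, genome)[lo:hi]


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard nuclear codon table.

    Translation stops at (and includes) the first stop codon, rendered
    ``"*"``. A trailing partial codon is ignored with a
    :class:`TranslationWarning`.
    """
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(cds) % 3:
        warnings.warn(
            f"trailing partial codon of length {len(cds) % 3} ignored",
            TranslationWarning,
            stacklevel=2,
        )
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        try:
            aa = CODON_TABLE[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at offset {i}") from None
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


# ---------------------------------------------------------------------------
# positional labels (c.-notation semantics)
# ---------------------------------------------------------------------------

class Region(str, Enum):
    CDS = "cds"
    UTR5 = "five_prime_utr"
    UTR3 = "three_prime_utr"
    INTRON = "intron"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    NONCODING_EXON = "noncoding_exon"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class PositionLabel:
    """Classification of a genomic position relative to one transcript.

    ``c`` is the HGVS-style coordinate string (without the ``c.`` prefix) for
    transcript-overlapping positions: a CDS offset (``"151"``), a 5'UTR
    offset (``"-12"``), a 3'UTR offset (``"*45"``), or an intronic anchor
    with signed offset (``"1716+19"``).
    """

    region: Region
    c: str | None = None
    cds_offset: int | None = None  # 1-based for CDS positions
    intron_offset: int | None = None  # signed, for intronic positions
    distance: int | None = None  # for upstream/downstream


def _exonic_c_label(transcript: TranscriptModel, spliced_idx: int) -> PositionLabel:
    if not transcript.is_coding:
        return PositionLabel(Region.NONCODING_EXON, c=str(spliced_idx + 1))
    lo, hi = transcript.cds_spliced_interval
    if spliced_idx < lo:
        return PositionLabel(Region.UTR5, c=str(spliced_idx - lo))
    if spliced_idx >= hi:
        return PositionLabel(Region.UTR3, c=f"*{spliced_idx - hi + 1}")
    off = spliced_idx - lo + 1
    return PositionLabel(Region.CDS, c=str(off), cds_offset=off)


def map_genomic_position(
    transcript: TranscriptModel, pos: int, flank: int = FLANK_WINDOW
) -> PositionLabel:
    """Classify genomic position ``pos`` (0-based) relative to a transcript.

    Every position maps to exactly one label. Intronic positions are labelled
    relative to the nearest exonic base in c.-coordinates: ``+N`` after the
    donor for the 5' half of the intron, ``-N`` before the acceptor for the
    3' half (ties to the donor side).
    """
    idx = transcript.genomic_to_spliced(pos)
    if idx is not None:
        return _exonic_c_label(transcript, idx)
    if pos < transcript.start or pos >= transcript.end:
        if transcript.strand == "+":
            before = pos < transcript.start
            dist = transcript.start - pos if before else pos - transcript.end + 1
        else:
            before = pos >= transcript.end
            dist = pos - transcript.end + 1 if before else transcript.start - pos
        if dist > flank:
            return PositionLabel(Region.INTERGENIC, distance=dist)
        region = Region.UPSTREAM if before else Region.DOWNSTREAM
        return PositionLabel(region, distance=dist)
    # intronic: locate the flanking exons in genomic order
    prev_exon = next_exon = None
    for e in transcript.exons:
        if e.end <= pos:
            prev_exon = e
        elif e.start > pos and next_exon is None:
            next_exon = e
    assert prev_exon is not None and next_exon is not None
    if transcript.strand == "+":
        donor_idx = transcript.genomic_to_spliced(prev_exon.end - 1)
        acceptor_idx = transcript.genomic_to_spliced(next_exon.start)
        d_donor = pos - prev_exon.end + 1
        d_acceptor = next_exon.start - pos
    else:
        donor_idx = transcript.genomic_to_spliced(next_exon.start)
        acceptor_idx = transcript.genomic_to_spliced(prev_exon.end - 1)
        d_donor = next_exon.start - pos
        d_acceptor = pos - prev_exon.end + 1
    if d_donor <= d_acceptor:
        anchor = _exonic_c_label(transcript, donor_idx)
        return PositionLabel(
            Region.INTRON, c=f"{anchor.c}+{d_donor}", intron_offset=d_donor
        )
    anchor = _exonic_c_label(transcript, acceptor_idx)
    return PositionLabel(
        Region.INTRON, c=f"{anchor.c}-{d_acceptor}", intron_offset=-d_acceptor
    )
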