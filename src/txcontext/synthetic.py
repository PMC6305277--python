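"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the structural features the analysis depends on rather
than realistic human genomics: multi-transcript genes whose isoforms give
divergent impacts for the same variant (via three divergence motifs:
exon skipping, an alternative splice boundary shifting the reading frame, and
a downstream coding start that turns a coding position into 5'UTR),
multi-submitter significance records, tissue-structured expression with
planted tissue-enriched genes, gene sets assembled to exact affected
fractions, and configuration-model scale-free interaction networks.

Every planted expectation is verified at generation time against the naive
oracle annotator (:mod:`txcontext.oracle`) or by direct computation, and
recorded in a serializable :class:`TruthBundle`. All generators are pure
functions of (parameters, seed); one top-level seed derives independent
per-generator substreams, so adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import clinvar, network as network_mod
from .burden import GeneSet, GeneSetCollection, write_gmt
from .clinvar import (
    Significance,
    SignificanceClass,
    SubmitterAssertion,
    VariantAssertionRecord,
    classify_significance,
    write_assertion_table,
)
from .consequence import Variant, annotate_gene, normalize
from .gene_models import (
    DEFAULT_BIOTYPE_WHITELIST,
    Biotype,
    ExonInterval,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    write_fasta,
    write_gtf,
)
from .oracle import oracle_consequence

__all__ = [
    "TruthBundle",
    "case_fixtures",
    "simulate_bundle",
    "simulate_expression",
    "simulate_genesets",
    "simulate_genome",
    "simulate_network",
    "simulate_variant_cohort",
    "substream",
]

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

#: substream indices: adding a generator appends a key, never renumbers
_STREAMS = {"genome": 0, "cohort": 1, "expression": 2, "genesets": 3, "network": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent per-generator random stream derived from one top seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


def variant_key(v: Variant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


@dataclass
class TruthBundle:
    """Machine-readable planted truth, sufficient to re-derive expectations."""

    seed: int
    params: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)  # gene_id -> motif/witness/impacts
    variant_classes: dict = field(default_factory=dict)  # key -> class
    witness_keys: list = field(default_factory=list)
    transcript_affected: dict = field(default_factory=dict)  # class -> [genes]
    expression: dict = field(default_factory=dict)
    genesets: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# ===========================================================================
# genome + transcript models
# ===========================================================================

@dataclass
class _LocalGene:
    """A gene under construction, in local plus-strand coordinates."""

    seq: bytearray
    transcripts: list[dict]  # exons (local), cds (local), biotype
    witness: tuple[int, str, str] | None  # (local pos, ref, alt)
    motif: str | None


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _build_local_gene(
    rng: np.random.Generator, n_tx: int, motif: str | None
) -> _LocalGene:
    """Construct one gene in local coordinates (always plus strand here;
    mirroring to minus strand happens at placement)."""
    n_exons = int(rng.integers(3, 6))
    n_codons = int(rng.integers(60, 121))
    # internal exon boundaries at codon multiples; every exon >= 10 codons
    while True:
        cuts = sorted(rng.choice(np.arange(10, n_codons - 9), size=n_exons - 1, replace=False))
        parts = np.diff([0, *cuts, n_codons])
        if (parts >= 10).all():
            break
    u5 = int(rng.integers(20, 41))
    u3 = int(rng.integers(60, 101))
    introns = [int(rng.integers(80, 201)) for _ in range(n_exons - 1)]

    cds = list("ATG" + _random_codons(rng, n_codons - 2) + "TAA")

    # witness target and motif edits operate on codon indices (0-based)
    exon_codon_start = np.concatenate([[0], np.cumsum(parts)])[:-1]

    def codon_slice(i: int) -> slice:
        return slice(3 * i, 3 * i + 3)

    witness_codon = None
    internal = list(range(1, n_exons - 1))
    skip_exon = int(rng.choice(internal)) if internal else None
    downstream_atg_codon = None
    shift_exon = None

    if motif == "skip" and skip_exon is not None:
        lo = int(exon_codon_start[skip_exon]) + 3
        hi = int(exon_codon_start[skip_exon] + parts[skip_exon]) - 3
        witness_codon = int(rng.integers(lo, hi))
    elif motif == "frameshift" and internal:
        shift_exon = int(rng.choice(internal))
        lo = int(exon_codon_start[shift_exon]) + 3
        hi = int(exon_codon_start[shift_exon] + parts[shift_exon]) - 3
        witness_codon = int(rng.integers(lo, hi))
    elif motif == "utr_start":
        # downstream ATG at roughly mid-CDS, witness upstream of it
        downstream_atg_codon = n_codons // 2
        cds[codon_slice(downstream_atg_codon)] = list("ATG")
        witness_codon = int(rng.integers(2, downstream_atg_codon - 2))
    if witness_codon is not None:
        cds[codon_slice(witness_codon)] = list("CAA")

    # --- lay out the local sequence ---------------------------------------
    seq = bytearray()
    exons: list[tuple[int, int]] = []
    cds_str = "".join(cds)
    cds_cursor = 0
    seq += _random_bases(rng, u5).encode()
    for i, p in enumerate(parts):
        if i == 0:
            start = 0
        else:
            seq += _random_bases(rng, introns[i - 1]).encode()
            start = len(seq)
        if i == 0:
            start = len(seq) - u5  # exon 1 includes the 5'UTR
        chunk = cds_str[cds_cursor : cds_cursor + 3 * int(p)]
        cds_cursor += 3 * int(p)
        seq += chunk.encode()
        exons.append((start, len(seq)))
    # extend last exon with the 3'UTR
    utr3_start = len(seq)
    seq += _random_bases(rng, u3).encode()
    exons[-1] = (exons[-1][0], len(seq))
    cds_start_local = u5
    cds_end_local = utr3_start

    transcripts: list[dict] = [
        {"exons": exons, "cds": (cds_start_local, cds_end_local), "biotype": "protein_coding"}
    ]

    # --- alternative transcripts ------------------------------------------
    def add_skip(exon_idx: int) -> None:
        alt = [e for j, e in enumerate(exons) if j != exon_idx]
        transcripts.append(
            {"exons": alt, "cds": (cds_start_local, cds_end_local), "biotype": "protein_coding"}
        )

    if motif == "skip" and skip_exon is not None:
        add_skip(skip_exon)
    elif motif == "frameshift" and shift_exon is not None:
        # acceptor moved 1 base into the intron: reading frame shifts by +1
        alt = list(exons)
        a, b = alt[shift_exon]
        seq[a - 1 : a] = b"G"
        alt[shift_exon] = (a - 1, b)
        # guarantee a stop for the shifted frame inside the 3'UTR
        spliced_before = sum(
            e2 - e1 for e1, e2 in alt[: len(alt) - 1]
        )  # all full exons before the last
        last_a, _ = alt[-1]
        # spliced offset of a last-exon position x is spliced_before + x-last_a
        def t2_frame_ok(x: int) -> bool:
            off = spliced_before + (x - last_a) - cds_start_local
            return off % 3 == 0

        x = utr3_start + 6
        while not t2_frame_ok(x):
            x += 1
        seq[x : x + 3] = b"TAA"
        transcripts.append(
            {"exons": alt, "cds": (cds_start_local, x + 3), "biotype": "protein_coding"}
        )
    elif motif == "utr_start" and downstream_atg_codon is not None:
        # locate the genomic (local) position of the downstream ATG
        target = 3 * downstream_atg_codon
        off = 0
        atg_local = None
        for (a, b) in exons:
            lo = max(a, cds_start_local)
            hi = min(b, cds_end_local)
            if hi <= lo:
                continue
            if off <= target < off + (hi - lo):
                atg_local = lo + (target - off)
                break
            off += hi - lo
        assert atg_local is not None
        transcripts.append(
            {"exons": exons, "cds": (atg_local, cds_end_local), "biotype": "protein_coding"}
        )

    # remaining isoforms: skip some other internal exon, or a non-coding copy
    other_internal = [j for j in internal if j != skip_exon]
    while len(transcripts) < n_tx:
        if other_internal and rng.random() < 0.7:
            add_skip(other_internal[int(rng.integers(0, len(other_internal)))])
        else:
            transcripts.append(
                {"exons": exons, "cds": None, "biotype": "processed_transcript"}
            )

    witness = None
    if witness_codon is not None:
        # first base of the planted CAA codon, in local coordinates
        target = 3 * witness_codon
        off = 0
        for (a, b) in exons:
            lo = max(a, cds_start_local)
            hi = min(b, cds_end_local)
            if hi <= lo:
                continue
            if off <= target < off + (hi - lo):
                witness = (lo + (target - off), "C", "T")
                break
            off += hi - lo
    return _LocalGene(seq=seq, transcripts=transcripts, witness=witness, motif=motif)


def _mirror(local: _LocalGene) -> _LocalGene:
    """Reverse-complement a local gene (turning it into a minus-strand gene)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(local.seq)
    seq = bytearray(
        "".join(comp[c] for c in reversed(local.seq.decode())).encode()
    )
    txs = []
    for t in local.transcripts:
        exons = sorted(((L - b, L - a) for a, b in t["exons"]))
        cds = None if t["cds"] is None else (L - t["cds"][1], L - t["cds"][0])
        txs.append({"exons": exons, "cds": cds, "biotype": t["biotype"]})
    wit = None
    if local.witness is not None:
        pos, ref, alt = local.witness
        wit = (L - 1 - pos, comp[ref], comp[alt])
    return _LocalGene(seq=seq, transcripts=txs, witness=wit, motif=local.motif)


def simulate_genome(
    n_genes: int = 50,
    transcripts_per_gene: tuple[int, int] = (2, 4),
    seed: int = 0,
    divergent_fraction: float = 0.6,
    n_chromosomes: int = 3,
    spacer: int = 10_000,
) -> tuple[GenomeSequence, list[GeneModel], TruthBundle]:
    """Random multi-transcript genes with planted divergence motifs.

    A ``divergent_fraction`` of genes carries one of three motifs with a
    planted witness variant whose per-transcript impacts are verified with
    the oracle annotator and recorded in the returned truth bundle.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo_tx, hi_tx = transcripts_per_gene
    if lo_tx < 1 or hi_tx < lo_tx:
        raise ValueError("bad transcripts_per_gene range")
    if hi_tx == 1 and divergent_fraction > 0:
        warnings.warn(
            "single-transcript genes cannot carry divergent motifs; "
            "no transcript-affected genes will be planted"
        )
    rng = substream(seed, "genome")
    motifs = ("skip", "frameshift", "utr_start")

    chrom_parts: dict[str, list] = {f"chr{i + 1}": [] for i in range(n_chromosomes)}
    cursors = {c: 0 for c in chrom_parts}
    truth = TruthBundle(
        seed=seed,
        params={
            "n_genes": n_genes,
            "transcripts_per_gene": list(transcripts_per_gene),
            "divergent_fraction": divergent_fraction,
        },
    )
    genes: list[GeneModel] = []
    witnesses: dict[str, tuple[str, int, str, str]] = {}

    for gi in range(n_genes):
        gene_id = f"G{gi:04d}"
        chrom = f"chr{gi % n_chromosomes + 1}"
        n_tx = int(rng.integers(lo_tx, hi_tx + 1))
        divergent = hi_tx > 1 and rng.random() < divergent_fraction
        motif = motifs[int(rng.integers(0, 3))] if divergent else None
        if motif is not None and n_tx < 2:
            n_tx = 2
        local = _build_local_gene(rng, n_tx, motif)
        if rng.random() < 0.5:
            local = _mirror(local)
            strand = "-"
        else:
            strand = "+"

        pad = spacer + int(rng.integers(0, 500))
        chrom_parts[chrom].append(_random_bases(rng, pad))
        cursors[chrom] += pad
        offset = cursors[chrom]
        chrom_parts[chrom].append(local.seq.decode())
        cursors[chrom] += len(local.seq)

        txs = []
        for ti, t in enumerate(local.transcripts):
            cds = t["cds"]
            txs.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.T{ti + 1}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(
                        ExonInterval(offset + a, offset + b) for a, b in t["exons"]
                    ),
                    cds_start=None if cds is None else offset + cds[0],
                    cds_end=None if cds is None else offset + cds[1],
                    biotype=Biotype(t["biotype"]),
                )
            )
        gene = GeneModel(gene_id=gene_id, symbol=f"SYM{gi:04d}", transcripts=tuple(txs))
        genes.append(gene)
        entry: dict = {"motif": local.motif, "strand": strand}
        if local.witness is not None:
            pos, ref, alt = local.witness
            witnesses[gene_id] = (chrom, offset + pos + 1, ref, alt)
            entry["witness"] = {
                "chrom": chrom,
                "pos": offset + pos + 1,
                "ref": ref,
                "alt": alt,
            }
        truth.genes[gene_id] = entry

    genome = GenomeSequence({c: "".join(p) + _random_bases(rng, 1000) for c, p in chrom_parts.items()})

    # verify every planted witness with the oracle annotator
    by_id = {g.gene_id: g for g in genes}
    for gene_id, (chrom, pos, ref, alt) in list(witnesses.items()):
        v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
        impacts = {}
        for tx in by_id[gene_id].transcripts:
            if tx.biotype in DEFAULT_BIOTYPE_WHITELIST:
                _, impact = oracle_consequence(v, tx, genome)
                impacts[tx.transcript_id] = impact.value
        if len(set(impacts.values())) < 2:
            # rare: the shifted frame happened to give an equally severe call
            del witnesses[gene_id]
            truth.genes[gene_id].pop("witness", None)
            truth.genes[gene_id]["motif"] = None
        else:
            truth.genes[gene_id]["expected_impacts"] = impacts
    return genome, genes, truth


# ===========================================================================
# variant cohort
# ===========================================================================

_PATTERNS = {
    SignificanceClass.PATHOGENIC: (
        (Significance.PATHOGENIC,),
        (Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC),
        (Significance.LIKELY_PATHOGENIC, Significance.PATHOGENIC),
        (Significance.PATHOGENIC, Significance.OTHER),
    ),
    SignificanceClass.VUS: (
        (Significance.UNCERTAIN,),
        (Significance.UNCERTAIN, Significance.LIKELY_PATHOGENIC),
        (Significance.PATHOGENIC, Significance.BENIGN),
        (Significance.LIKELY_PATHOGENIC, Significance.LIKELY_BENIGN),
    ),
    SignificanceClass.BENIGN: (
        (Significance.BENIGN,),
        (Significance.BENIGN, Significance.LIKELY_BENIGN),
        (Significance.LIKELY_BENIGN, Significance.BENIGN),
        (Significance.BENIGN, Significance.OTHER),
    ),
    SignificanceClass.EXCLUDED: (
        (Significance.LIKELY_BENIGN,),
        (Significance.OTHER,),
    ),
}


def _make_submitters(
    cls: SignificanceClass, rng: np.random.Generator
) -> tuple[SubmitterAssertion, ...]:
    pattern = _PATTERNS[cls][int(rng.integers(0, len(_PATTERNS[cls])))]
    subs = tuple(
        SubmitterAssertion(sig, has_assertion_criteria=(i == 0))
        for i, sig in enumerate(pattern)
    )
    rec = VariantAssertionRecord(
        variant=Variant(chrom="chr1", pos=1, ref="A", alt="C"),
        gene_id="x",
        submitters=subs,
    )
    assert classify_significance(rec) == cls, (cls, pattern)
    return subs


def simulate_variant_cohort(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    truth: TruthBundle,
    class_mix: dict[str, float] | None = None,
    n_variants: int = 1000,
    seed: int = 0,
    indel_fraction: float = 0.15,
    excluded_fraction: float = 0.0,
) -> tuple[list[VariantAssertionRecord], TruthBundle]:
    """ClinVar-style records whose submitter patterns classify
    deterministically; witness variants of planted genes are always
    PATHOGENIC. Truth gains per-variant classes and the per-class
    transcript-affected gene sets (computed with the oracle annotator)."""
    mix = class_mix or {"PATHOGENIC": 0.4, "VUS": 0.35, "BENIGN": 0.25}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = substream(seed, "cohort")
    by_id = {g.gene_id: g for g in genes}

    witness: list[tuple[str, Variant]] = []
    for gene_id, entry in truth.genes.items():
        w = entry.get("witness")
        if w:
            witness.append(
                (gene_id, Variant(chrom=w["chrom"], pos=w["pos"], ref=w["ref"], alt=w["alt"]))
            )
    if n_variants < len(witness):
        raise ValueError(
            f"n_variants={n_variants} below planted-witness requirement {len(witness)}"
        )

    records: list[VariantAssertionRecord] = []
    seen: set[str] = set()
    for gene_id, v in witness:
        v = normalize(v, genome)
        seen.add(variant_key(v))
        records.append(
            VariantAssertionRecord(
                variant=v,
                gene_id=gene_id,
                submitters=_make_submitters(SignificanceClass.PATHOGENIC, rng),
            )
        )
        truth.variant_classes[variant_key(v)] = "PATHOGENIC"
        truth.witness_keys.append(variant_key(v))

    class_names = sorted(mix)
    probs = np.array([mix[c] for c in class_names])
    gene_list = list(genes)
    tries = 0
    while len(records) < n_variants:
        tries += 1
        if tries > 50 * n_variants:
            raise RuntimeError("could not place enough unique variants")
        gene = gene_list[int(rng.integers(0, len(gene_list)))]
        pos0 = int(rng.integers(gene.start - 200, gene.end + 200))
        chrom_seq = genome[gene.chrom]
        if not 1 <= pos0 < len(chrom_seq) - 10:
            continue
        r = rng.random()
        if r < 1 - indel_fraction:  # SNV
            ref = chrom_seq[pos0]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref or ref not in "ACGT":
                continue
        elif r < 1 - indel_fraction / 2:  # deletion of 1-3 bases
            k = int(rng.integers(1, 4))
            ref = chrom_seq[pos0 : pos0 + 1 + k]
            alt = ref[0]
            if set(ref) - set("ACGT"):
                continue
        else:  # insertion of 1-3 bases
            ref = chrom_seq[pos0]
            if ref not in "ACGT":
                continue
            alt = ref + _random_bases(rng, int(rng.integers(1, 4)))
        try:
            v = normalize(Variant(chrom=gene.chrom, pos=pos0 + 1, ref=ref, alt=alt), genome)
        except ValueError:
            continue
        key = variant_key(v)
        if key in seen:
            continue
        seen.add(key)
        if excluded_fraction and rng.random() < excluded_fraction:
            cls = SignificanceClass.EXCLUDED
        else:
            cls = SignificanceClass(class_names[int(rng.choice(len(class_names), p=probs))])
        records.append(
            VariantAssertionRecord(variant=v, gene_id=gene.gene_id, submitters=_make_submitters(cls, rng))
        )
        truth.variant_classes[key] = cls.value

    # per-class transcript-affected truth, computed with the (oracle-
    # validated) annotator so downstream recovery is exact by construction
    affected: dict[str, set[str]] = {"PATHOGENIC": set(), "VUS": set(), "BENIGN": set()}
    for rec in records:
        cls = classify_significance(rec)
        if cls.value not in affected:
            continue
        calls = annotate_gene(
            rec.variant, by_id[rec.gene_id], genome, DEFAULT_BIOTYPE_WHITELIST
        )
        if len({c.impact for c in calls}) >= 2:
            affected[cls.value].add(rec.gene_id)
    truth.transcript_affected = {k: sorted(v) for k, v in affected.items()}
    return records, truth


def write_vcf(
    records: Sequence[VariantAssertionRecord],
    genome: GenomeSequence,
    path: str | Path,
) -> None:
    """Site-only VCF v4.2 of the cohort, coordinate-sorted."""
    rows = sorted(records, key=lambda r: (r.variant.chrom, r.variant.pos, r.variant.ref, r.variant.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.chromosomes:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in rows:
            v = rec.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\tGENE={rec.gene_id}\n"
            )


# ===========================================================================
# expression
# ===========================================================================

def dummy_gene_models(n_genes: int, transcripts_per_gene: int = 2) -> list[GeneModel]:
    """Minimal placeholder gene models (single-exon, non-overlapping) for
    expression-only simulations where no genome sequence is needed."""
    genes = []
    for gi in range(n_genes):
        start = 1000 * gi
        txs = tuple(
            TranscriptModel(
                transcript_id=f"G{gi:04d}.T{ti + 1}",
                gene_id=f"G{gi:04d}",
                chrom="chr1",
                strand="+",
                exons=(ExonInterval(start, start + 300),),
                biotype=Biotype.PROTEIN_CODING,
            )
            for ti in range(transcripts_per_gene)
        )
        genes.append(GeneModel(gene_id=f"G{gi:04d}", symbol=f"SYM{gi:04d}", transcripts=txs))
    return genes

def simulate_expression(
    genes: Sequence[GeneModel],
    n_tissues: int = 10,
    samples_per_tissue: int = 20,
    planted_fraction: float = 0.1,
    effect_log2: float = 6.0,
    sigma: float = 0.5,
    seed: int = 0,
    truth: TruthBundle | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, TruthBundle]:
    """Tissue-structured transcript×sample TPM matrix with planted
    tissue-enriched genes.

    log2 abundance = transcript baseline + gene-level tissue shift (planted
    genes only: ``effect_log2`` in a random 1–3 tissue subset) + N(0, σ)
    noise. Planted genes draw top-quintile baselines so the percentile
    criterion is satisfiable. TPM is emitted as ``2^x − 1`` clipped at 0 so
    the pipeline's log transform round-trips.
    """
    if n_tissues < 2 or samples_per_tissue < 2:
        raise ValueError("need >= 2 tissues and >= 2 samples per tissue")
    if planted_fraction > 0.5:
        raise ValueError(
            "planted_fraction > 0.5 makes the percentile criterion unsatisfiable"
        )
    rng = substream(seed, "expression")
    truth = truth or TruthBundle(seed=seed)
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    n_planted = int(round(planted_fraction * n_genes))
    planted = sorted(rng.choice(gene_ids, size=n_planted, replace=False).tolist())
    planted_set = set(planted)

    baselines = rng.normal(3.0, 2.0, size=n_genes)
    q80 = float(np.quantile(baselines, 0.8))
    tissue_names = [f"tissue{t + 1:02d}" for t in range(n_tissues)]
    sample_names = [
        f"{t}_s{s + 1:02d}" for t in tissue_names for s in range(samples_per_tissue)
    ]
    sample_tissue = pd.Series(
        [t for t in tissue_names for _ in range(samples_per_tissue)],
        index=sample_names,
        name="tissue",
    )

    rows = {}
    tx_gene = {}
    planted_info = {}
    for gi, gene in enumerate(genes):
        base = baselines[gi]
        if gene.gene_id in planted_set:
            base = float(rng.uniform(q80, q80 + 2.0))
            k = int(rng.integers(1, min(3, n_tissues - 1) + 1))
            shifted = sorted(rng.choice(tissue_names, size=k, replace=False).tolist())
            planted_info[gene.gene_id] = {"tissues": shifted, "effect_log2": effect_log2}
        else:
            shifted = []
        shift = np.array(
            [effect_log2 if t in shifted else 0.0 for t in sample_tissue], dtype=float
        )
        for ti, tx in enumerate(gene.transcripts):
            tx_base = base if ti == 0 else base - float(rng.uniform(1.0, 3.0))
            log_vals = tx_base + shift + rng.normal(0.0, sigma, size=len(sample_names))
            rows[tx.transcript_id] = np.clip(np.exp2(log_vals) - 1.0, 0.0, None)
            tx_gene[tx.transcript_id] = gene.gene_id

    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_names)
    truth.expression = {
        "planted": planted_info,
        "params": {
            "n_tissues": n_tissues,
            "samples_per_tissue": samples_per_tissue,
            "planted_fraction": planted_fraction,
            "effect_log2": effect_log2,
            "sigma": sigma,
        },
    }
    return values, sample_tissue, pd.Series(tx_gene, name="gene_id"), truth


# ===========================================================================
# gene sets
# ===========================================================================

def simulate_genesets(
    universe: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    target_fractions: Sequence[float],
    affected: Sequence[str],
    seed: int = 0,
    prefix: str = "SET",
    truth: TruthBundle | None = None,
) -> tuple[GeneSetCollection, TruthBundle]:
    """Gene sets assembled to exact affected fractions: set *i* targets
    ``target_fractions[i % len(target_fractions)]`` and samples
    ``ceil(f·s)`` affected plus ``s − ceil(f·s)`` unaffected members."""
    rng = substream(seed, "genesets")
    truth = truth or TruthBundle(seed=seed)
    affected_pool = sorted(set(affected) & set(universe))
    unaffected_pool = sorted(set(universe) - set(affected))
    sets = []
    realized = {}
    for i in range(n_sets):
        f = float(target_fractions[i % len(target_fractions)])
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        n_aff = math.ceil(f * size)
        name = f"{prefix}{i:03d}"
        if n_aff > len(affected_pool) or size - n_aff > len(unaffected_pool):
            raise ValueError(
                f"set {name}: target fraction {f} unachievable with "
                f"{len(affected_pool)} affected / {len(unaffected_pool)} unaffected genes"
            )
        members = sorted(
            rng.choice(affected_pool, size=n_aff, replace=False).tolist()
            + rng.choice(unaffected_pool, size=size - n_aff, replace=False).tolist()
        )
        sets.append(GeneSet(name=name, members=frozenset(members), description=f"target={f}"))
        realized[name] = n_aff / size
    collection = GeneSetCollection(sets=tuple(sets), universe=frozenset(universe))
    truth.genesets[prefix] = {
        "target_fractions": list(map(float, target_fractions)),
        "realized_fractions": realized,
    }
    return collection, truth


# ===========================================================================
# interaction network
# ===========================================================================

def simulate_network(
    n_nodes: int = 2000,
    gamma_target: float = 2.7,
    seed: int = 0,
    node_labels: Sequence[str] | None = None,
    hub_genes: Sequence[str] = (),
    truth: TruthBundle | None = None,
) -> tuple[nx.Graph, TruthBundle]:
    """Scale-free graph: zipf degree sequence (capped at √n), paired by the
    configuration model, simplified to a simple graph.

    ``hub_genes`` (a subset of ``node_labels``) are assigned the largest
    degrees, planting a degree-biased gene set whose induced subgraph has a
    flatter degree distribution than random samples.
    """
    if gamma_target <= 2.0:
        raise ValueError("gamma_target must be > 2")
    rng = substream(seed, "network")
    truth = truth or TruthBundle(seed=seed)
    labels = list(node_labels) if node_labels is not None else [f"N{i:05d}" for i in range(n_nodes)]
    if len(labels) != n_nodes:
        raise ValueError("node_labels length must equal n_nodes")

    cap = max(int(round(n_nodes**0.5)), 10)
    degrees = rng.zipf(gamma_target, size=n_nodes)
    n_capped = int(np.sum(degrees > cap))
    if n_capped:
        warnings.warn(f"{n_capped} degrees capped at {cap} (heavy tail)")
    degrees = np.clip(degrees, 1, cap)
    odd_adjusted = False
    if degrees.sum() % 2:
        degrees[int(np.argmin(degrees))] += 1
        odd_adjusted = True

    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = network_mod.simplify(g)

    order = np.argsort(-degrees, kind="stable")
    mapping: dict[int, str] = {}
    hubs = list(hub_genes)
    rng.shuffle(hubs)
    others = [l for l in labels if l not in set(hub_genes)]
    rng.shuffle(others)
    for rank, node_idx in enumerate(order):
        if rank < len(hubs):
            mapping[int(node_idx)] = hubs[rank]
        else:
            mapping[int(node_idx)] = others[rank - len(hubs)]
    g = nx.relabel_nodes(g, mapping)

    truth.network = {
        "gamma_target": gamma_target,
        "n_nodes": n_nodes,
        "degree_cap": cap,
        "n_capped": n_capped,
        "odd_sum_adjusted": odd_adjusted,
        "hub_genes": sorted(hub_genes),
    }
    return g, truth


# ===========================================================================
# full bundle
# ===========================================================================

def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 50,
    transcripts_per_gene: tuple[int, int] = (2, 4),
    divergent_fraction: float = 0.6,
    n_variants: int = 1000,
    n_tissues: int = 10,
    samples_per_tissue: int = 20,
    planted_expression_fraction: float = 0.1,
    effect_log2: float = 6.0,
    sigma: float = 0.5,
    n_pathways: int = 12,
    n_diseases: int = 8,
    network_nodes: int = 2000,
    network_gamma: float = 3.5,
) -> TruthBundle:
    """Generate every pipeline input into ``out_dir`` plus ``truth.json``.

    File names are fixed: genome.fa, annotation.gtf, variants.vcf,
    assertions.tsv, expression.tsv, samples.tsv, tx2gene.tsv, pathways.gmt,
    diseases.gmt, network.tsv, truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(
        n_genes=n_genes,
        transcripts_per_gene=transcripts_per_gene,
        seed=seed,
        divergent_fraction=divergent_fraction,
    )
    write_fasta(genome, out / "genome.fa")
    write_gtf(genes, out / "annotation.gtf")

    records, truth = simulate_variant_cohort(
        genome, genes, truth, n_variants=n_variants, seed=seed
    )
    write_vcf(records, genome, out / "variants.vcf")
    write_assertion_table(records, out / "assertions.tsv")

    values, sample_tissue, tx_gene, truth = simulate_expression(
        genes,
        n_tissues=n_tissues,
        samples_per_tissue=samples_per_tissue,
        planted_fraction=planted_expression_fraction,
        effect_log2=effect_log2,
        sigma=sigma,
        seed=seed,
        truth=truth,
    )
    values.round(4).to_csv(out / "expression.tsv", sep="\t", index_label="transcript_id")
    sample_tissue.to_frame().to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    tx_gene.to_frame().to_csv(out / "tx2gene.tsv", sep="\t", index_label="transcript_id")

    universe = [g.gene_id for g in genes]
    affected = truth.transcript_affected.get("PATHOGENIC", [])
    n_aff, n_unaff = len(affected), n_genes - len(affected)
    # fixed set size, chosen so both pools can serve the target fractions
    size = min(12, max(n_aff, 1), max(n_unaff, 1), max(n_genes // 2, 1))

    def feasible(fracs: tuple[float, ...]) -> tuple[float, ...]:
        return tuple(
            f
            for f in fracs
            if math.ceil(f * size) <= n_aff and size - math.ceil(f * size) <= n_unaff
        )

    pathway_fracs = feasible((0.0, 0.25, 0.5, 1.0))
    disease_fracs = feasible((0.0, 0.5, 0.75, 1.0))
    if size >= 2 and pathway_fracs and disease_fracs:
        pathways, truth = simulate_genesets(
            universe, n_pathways, (size, size), pathway_fracs, affected, seed=seed,
            prefix="PWY", truth=truth,
        )
        write_gmt(pathways, out / "pathways.gmt")
        diseases, truth = simulate_genesets(
            universe, n_diseases, (size, size), disease_fracs, affected, seed=seed,
            prefix="DIS", truth=truth,
        )
        write_gmt(diseases, out / "diseases.gmt")
    else:
        warnings.warn("gene-set planting skipped: pools too small for targets")

    # the planted tissue-enriched genes are wired as network hubs, so the
    # affected-gene subgraph has a flatter degree distribution than random
    # samples — the contrast the network stage is meant to expose
    filler = [f"NPC{i:05d}" for i in range(network_nodes - len(universe))]
    graph, truth = simulate_network(
        n_nodes=network_nodes,
        gamma_target=network_gamma,
        seed=seed,
        node_labels=universe + filler,
        hub_genes=sorted(truth.expression["planted"]),
        truth=truth,
    )
    network_mod.write_edge_list(graph, out / "network.tsv")

    truth.params.update(
        {
            "n_variants": n_variants,
            "network_nodes": network_nodes,
            "network_gamma": network_gamma,
        }
    )
    truth.to_json(out / "truth.json")
    return truth


# ===========================================================================
# deterministic case-example fixtures
# ===========================================================================

def _blank(n: int) -> bytearray:
    return bytearray(b"T" * n)


def _set(seq: bytearray, start: int, text: str) -> None:
    seq[start : start + len(text)] = text.encode()


def case_fixtures() -> dict:
    """Hand-crafted fixtures reproducing the structure of published case
    examples on fully synthetic coordinates.

    * ``fig`` — one variant, three isoforms, impacts HIGH / MODERATE /
      MODIFIER (nonsense in the canonical frame, missense in a frame-shifted
      isoform, intronic in an exon-skipping isoform);
    * ``chd7_like`` — nonsense at codon 579 of a long transcript
      (``p.Gln579*``) that is intronic, 19 bases past the donor after
      c.1716, in a short transcript (``c.1716+19C>T``);
    * ``arid1a_like`` — ``p.Gly1255Glu`` missense in the canonical
      transcript; the exon is absent from the alternative transcript;
    * ``kmt2c_like`` — nonsense in the canonical transcript, 5'UTR in an
      isoform whose coding start lies downstream of the variant.
    """
    fixtures: dict = {}

    # ------------------------------------------------------- three-isoform
    seq = _blank(700)
    _set(seq, 100, "C" * 30)             # 5'UTR
    _set(seq, 130, "ATG" + "GCA" * 29)   # exon1 coding: codons 1-30
    _set(seq, 299, "G")                  # extra base of the alt acceptor
    _set(seq, 300, "GCA" * 40)           # exon2 coding: codons 31-70
    _set(seq, 357, "GAG")                # codon 50
    _set(seq, 360, "CAA")                # codon 51: the witness target
    _set(seq, 500, "GCA" * 10)           # exon3 coding: codons 71-80
    _set(seq, 530, "TAA")                # canonical stop
    _set(seq, 533, "CC")
    _set(seq, 535, "TAA")                # stop for the shifted frame
    e1, e2, e3 = ExonInterval(100, 220), ExonInterval(300, 420), ExonInterval(500, 620)
    e2b = ExonInterval(299, 420)
    common = dict(gene_id="GFIG", chrom="chrFIG", strand="+")
    tx_a = TranscriptModel(transcript_id="GFIG.T1", exons=(e1, e2, e3), cds_start=130, cds_end=533, **common)
    tx_b = TranscriptModel(transcript_id="GFIG.T2", exons=(e1, e2b, e3), cds_start=130, cds_end=538, **common)
    tx_c = TranscriptModel(transcript_id="GFIG.T3", exons=(e1, e3), cds_start=130, cds_end=533, **common)
    fixtures["fig"] = {
        "genome": {"chrFIG": seq.decode()},
        "gene": GeneModel(gene_id="GFIG", symbol="FIG1A", transcripts=(tx_a, tx_b, tx_c)),
        "variant": Variant(chrom="chrFIG", pos=361, ref="C", alt="T"),
    }

    # ------------------------------------------------------------ CHD7-like
    seq = _blank(2300)
    _set(seq, 200, "C" * 50)                       # 5'UTR
    _set(seq, 250, "ATG" + "CAG" * 598 + "CAA")    # codons 1-600; codon 579 reset below
    _set(seq, 250 + 578 * 3, "CAA")                # codon 579 = Gln
    _set(seq, 2050, "TAA")                         # stop (codon 601)
    _set(seq, 2100, "CAGTAA")                      # short-isoform exon2: one codon + stop
    common = dict(gene_id="GCHD", chrom="chrCHD", strand="+")
    tx_long = TranscriptModel(
        transcript_id="GCHD.T1", exons=(ExonInterval(200, 2113),), cds_start=250, cds_end=2053, **common
    )
    tx_short = TranscriptModel(
        transcript_id="GCHD.T2",
        exons=(ExonInterval(200, 1966), ExonInterval(2100, 2166)),
        cds_start=250,
        cds_end=2106,
        **common,
    )
    fixtures["chd7_like"] = {
        "genome": {"chrCHD": seq.decode()},
        "gene": GeneModel(gene_id="GCHD", symbol="CHD7L", transcripts=(tx_long, tx_short)),
        "variant": Variant(chrom="chrCHD", pos=1985, ref="C", alt="T"),
    }

    # ---------------------------------------------------------- ARID1A-like
    seq = _blank(4500)
    _set(seq, 100, "C" * 30)                     # 5'UTR
    _set(seq, 130, "ATG" + "GCT" * 1199)         # exon1: codons 1-1200
    _set(seq, 3830, "GCT" * 100)                 # exon2: codons 1201-1300
    _set(seq, 3992, "GGA")                       # codon 1255 = Gly
    _set(seq, 4230, "GCT" * 10)                  # exon3: codons 1301-1310
    _set(seq, 4260, "TAA")                       # stop (codon 1311)
    common = dict(gene_id="GARI", chrom="chrARI", strand="+")
    exA = (ExonInterval(100, 3730), ExonInterval(3830, 4130), ExonInterval(4230, 4330))
    exB = (ExonInterval(100, 3730), ExonInterval(4230, 4330))
    tx_can = TranscriptModel(transcript_id="GARI.T1", exons=exA, cds_start=130, cds_end=4263, **common)
    tx_alt = TranscriptModel(transcript_id="GARI.T2", exons=exB, cds_start=130, cds_end=4263, **common)
    fixtures["arid1a_like"] = {
        "genome": {"chrARI": seq.decode()},
        "gene": GeneModel(gene_id="GARI", symbol="ARID1AL", transcripts=(tx_can, tx_alt)),
        "variant": Variant(chrom="chrARI", pos=3994, ref="G", alt="A"),
    }

    # ----------------------------------------------------------- KMT2C-like
    seq = _blank(1000)
    _set(seq, 100, "C" * 30)                     # 5'UTR
    _set(seq, 130, "ATG" + "GCT" * 89)           # exon1: codons 1-90
    _set(seq, 500, "GCT" * 100)                  # exon2 fill: codons 91-190
    _set(seq, 512, "CAA")                        # codon 95 = Gln (witness)
    _set(seq, 530, "ATG")                        # codon 101: downstream start
    _set(seq, 557, "TAA")                        # stop (codon 120)
    common = dict(gene_id="GKMT", chrom="chrKMT", strand="+")
    ex = (ExonInterval(100, 400), ExonInterval(500, 800))
    tx_can = TranscriptModel(transcript_id="GKMT.T1", exons=ex, cds_start=130, cds_end=560, **common)
    tx_alt = TranscriptModel(transcript_id="GKMT.T2", exons=ex, cds_start=530, cds_end=560, **common)
    fixtures["kmt2c_like"] = {
        "genome": {"chrKMT": seq.decode()},
        "gene": GeneModel(gene_id="GKMT", symbol="KMT2CL", transcripts=(tx_can, tx_alt)),
        "variant": Variant(chrom="chrKMT", pos=513, ref="C", alt="T"),
    }

    merged = GenomeSequence(
        {k: v for fx in fixtures.values() for k, v in fx["genome"].items()}
    )
    for fx in fixtures.values():
        fx["genome"] = merged
    return fixtures
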