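"""Orchestration: configuration, the end-to-end analysis, and the report.

``run_all`` executes the stages in order — annotate → classify significance →
transcript flags → expression flags → overlap → burden → network — skipping
any stage whose inputs are not configured, and returns an
:class:`AnalysisReport` whose JSON body is byte-identical across runs with
the same inputs, config and seed (the provenance timestamp is excluded from
the checksum scope).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import network as network_mod
from .burden import overlap_summary, read_gmt, summarize_collection
from .clinvar import (
    SignificanceClass,
    classify_significance,
    proportion_test,
    read_assertion_table,
)
from .consequence import annotate_gene, normalize, write_annotated_tsv
from .expression import Thresholds, flag_expression_affected, read_expression_tsv
from .gene_models import Biotype, read_fasta, read_gtf

__all__ = ["AnalysisConfig", "AnalysisReport", "run_all"]

_CLASSES = ("PATHOGENIC", "VUS", "BENIGN")


@dataclass
class AnalysisConfig:
    """All fixed constants of the analysis, with the published defaults."""

    genome: Path | None = None
    annotation: Path | None = None
    assertions: Path | None = None
    expression: Path | None = None
    samples: Path | None = None
    tx2gene: Path | None = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    networks: dict[str, Path] = field(default_factory=dict)

    percentile_min: float = 80.0
    p_max: float = 1e-30
    variance_ratio_min: float = 10.0
    burden_thresholds: tuple[float, float] = (0.25, 0.50)
    biotype_whitelist: tuple[str, ...] = (
        "protein_coding",
        "nonsense_mediated_decay",
        "retained_intron",
        "processed_transcript",
    )
    flank: int = 5000
    null_replicates: int = 100
    seed: int = 0
    exponent_method: str = "mle"
    network_betweenness: bool = True

    def validate(self) -> None:
        if not (0 < self.percentile_min < 100):
            raise ValueError("percentile_min must lie in (0, 100)")
        if self.p_max <= 0 or self.variance_ratio_min <= 0:
            raise ValueError("thresholds must be positive")
        lo, hi = self.burden_thresholds
        if not (0 <= lo <= hi <= 1):
            raise ValueError("burden thresholds must satisfy 0 <= lo <= hi <= 1")
        if not self.biotype_whitelist:
            raise ValueError("biotype whitelist must be non-empty")
        if self.null_replicates < 2:
            raise ValueError("null_replicates must be >= 2")
        for p in self._paths():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def _paths(self):
        yield from (self.genome, self.annotation, self.assertions, self.expression,
                    self.samples, self.tx2gene)
        yield from self.gene_sets.values()
        yield from self.networks.values()

    @property
    def whitelist(self) -> frozenset[Biotype]:
        return frozenset(Biotype(b) for b in self.biotype_whitelist)

    @classmethod
    def from_dir(cls, directory: str | Path, **overrides) -> "AnalysisConfig":
        """Config over a directory laid out by
        :func:`txcontext.synthetic.simulate_bundle` (missing files leave the
        corresponding stage unconfigured)."""
        d = Path(directory)

        def opt(name: str) -> Path | None:
            p = d / name
            return p if p.exists() else None

        gene_sets = {}
        for stem in ("pathways", "diseases"):
            p = d / f"{stem}.gmt"
            if p.exists():
                gene_sets[stem] = p
        networks = {}
        if (d / "network.tsv").exists():
            networks["ppi"] = d / "network.tsv"
        cfg = cls(
            genome=opt("genome.fa"),
            annotation=opt("annotation.gtf"),
            assertions=opt("assertions.tsv"),
            expression=opt("expression.tsv"),
            samples=opt("samples.tsv"),
            tx2gene=opt("tx2gene.tsv"),
            gene_sets=gene_sets,
            networks=networks,
            **overrides,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})

        def rel(p):
            return None if p is None else (base / p)

        kwargs = dict(
            genome=rel(inputs.get("genome")),
            annotation=rel(inputs.get("annotation")),
            assertions=rel(inputs.get("assertions")),
            expression=rel(inputs.get("expression")),
            samples=rel(inputs.get("samples")),
            tx2gene=rel(inputs.get("tx2gene")),
            gene_sets={k: base / v for k, v in (inputs.get("gene_sets") or {}).items()},
            networks={k: base / v for k, v in (inputs.get("networks") or {}).items()},
        )
        thr = raw.get("thresholds", {})
        for key in ("percentile_min", "p_max", "variance_ratio_min"):
            if key in thr:
                kwargs[key] = float(thr[key])
        if "burden" in thr:
            kwargs["burden_thresholds"] = tuple(float(x) for x in thr["burden"])
        net = raw.get("network", {})
        for key, cast in (
            ("null_replicates", int),
            ("seed", int),
            ("exponent_method", str),
        ):
            if key in net:
                kwargs[key] = cast(net[key])
        if "with_betweenness" in net:
            kwargs["network_betweenness"] = bool(net["with_betweenness"])
        if "biotype_whitelist" in raw:
            kwargs["biotype_whitelist"] = tuple(raw["biotype_whitelist"])
        if "flank" in raw:
            kwargs["flank"] = int(raw["flank"])
        return cls(**kwargs)


@dataclass
class AnalysisReport:
    """All result tables plus provenance; every number is recomputable from
    the inputs and the config."""

    sections: dict
    gene_flags: dict  # gene -> flags
    annotation_rows: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "sections": self.sections,
            "gene_flags": self.gene_flags,
            "provenance": self.provenance,
        }

    def body_checksum(self) -> str:
        """sha256 over the report body with volatile provenance removed."""
        d = copy.deepcopy(self.to_dict())
        d["provenance"].pop("timestamp", None)
        d["provenance"].pop("body_checksum", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        d = copy.deepcopy(self.to_dict())
        d["provenance"]["body_checksum"] = self.body_checksum()
        with open(out / "report.json", "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
        with open(out / "gene_flags.tsv", "w") as fh:
            cols = ["gene_id"] + [f"transcript_affected_{c}" for c in _CLASSES] + [
                "expression_affected",
                "in_overlap",
            ]
            fh.write("\t".join(cols) + "\n")
            for gene in sorted(self.gene_flags):
                flags = self.gene_flags[gene]
                fh.write(
                    "\t".join(
                        [gene]
                        + [str(int(flags.get(f"transcript_affected_{c}", False))) for c in _CLASSES]
                        + [
                            str(int(flags.get("expression_affected", False))),
                            str(int(flags.get("in_overlap", False))),
                        ]
                    )
                    + "\n"
                )
        if self.annotation_rows:
            write_annotated_tsv(self.annotation_rows, out / "annotation.tsv")
        if "burden" in self.sections and not self.sections["burden"].get("skipped"):
            with open(out / "burden.tsv", "w") as fh:
                fh.write("collection\tset\teffective_size\tflag\tfraction\n")
                for cname, block in sorted(self.sections["burden"].items()):
                    for flag, summ in sorted(block.items()):
                        for sname, frac in sorted(summ["fractions"].items()):
                            fh.write(
                                f"{cname}\t{sname}\t{summ['effective_sizes'][sname]}\t"
                                f"{flag}\t{frac:.6g}\n"
                            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: AnalysisConfig) -> AnalysisReport:
    """Execute every configured stage; unconfigured stages are marked
    skipped in the report."""
    config.validate()
    sections: dict = {}
    gene_flags: dict[str, dict] = {}
    annotation_rows: list = []

    genome = genes = None
    if config.genome and config.annotation:
        genome = read_fasta(config.genome)
        genes = read_gtf(config.annotation)

    # ---------------- annotation + significance + transcript flags --------
    affected_by_class: dict[str, set[str]] = {c: set() for c in _CLASSES}
    genes_with_class: dict[str, set[str]] = {c: set() for c in _CLASSES}
    if genome is not None and config.assertions:
        by_id = {g.gene_id: g for g in genes}
        records = read_assertion_table(config.assertions)
        class_counts = {c: 0 for c in _CLASSES}
        class_counts["EXCLUDED"] = 0
        n_calls = 0
        transcripts_hit: set[str] = set()
        for rec in records:
            cls = classify_significance(rec)
            class_counts[cls.value] += 1
            if cls is SignificanceClass.EXCLUDED or rec.gene_id not in by_id:
                continue
            variant = normalize(rec.variant, genome)
            calls = annotate_gene(
                variant, by_id[rec.gene_id], genome, config.whitelist, flank=config.flank
            )
            n_calls += len(calls)
            transcripts_hit.update(c.transcript_id for c in calls)
            for call in calls:
                annotation_rows.append((variant, rec.gene_id, call))
            genes_with_class[cls.value].add(rec.gene_id)
            if len({c.impact for c in calls}) >= 2:
                affected_by_class[cls.value].add(rec.gene_id)
        for c in _CLASSES:
            for g in genes_with_class[c]:
                gene_flags.setdefault(g, {})[f"transcript_affected_{c}"] = (
                    g in affected_by_class[c]
                )
        counts = {
            c: {
                "records": class_counts[c],
                "genes": len(genes_with_class[c]),
                "transcript_affected_genes": len(affected_by_class[c]),
            }
            for c in _CLASSES
        }
        counts["EXCLUDED"] = {"records": class_counts["EXCLUDED"]}
        section: dict = {
            "counts": counts,
            "n_consequence_calls": n_calls,
            "n_transcripts_annotated": len(transcripts_hit),
        }
        testable = [c for c in _CLASSES if genes_with_class[c]]
        if len(testable) >= 2:
            stat, p, eff = proportion_test(
                [len(affected_by_class[c]) for c in testable],
                [len(genes_with_class[c]) for c in testable],
            )
            section["proportion_test"] = {
                "classes": testable,
                "statistic": stat,
                "p_value": p,
                "effect_size": eff,
            }
        sections["transcript_affected"] = section
    else:
        sections["transcript_affected"] = {"skipped": True}

    # ---------------- expression flags ------------------------------------
    expression_affected: set[str] = set()
    if config.expression and config.samples and config.tx2gene:
        matrix = read_expression_tsv(config.expression, config.samples, config.tx2gene)
        thresholds = Thresholds(
            percentile_min=config.percentile_min,
            p_max=config.p_max,
            variance_ratio_min=config.variance_ratio_min,
        )
        flags = flag_expression_affected(matrix, thresholds)
        for gene, fl in flags.items():
            gene_flags.setdefault(gene, {})["expression_affected"] = fl.expression_affected
            if fl.expression_affected:
                expression_affected.add(gene)
        sections["expression_affected"] = {
            "n_genes": len(flags),
            "n_affected": len(expression_affected),
            "thresholds": asdict(thresholds),
        }
    else:
        sections["expression_affected"] = {"skipped": True}

    # ---------------- overlap ---------------------------------------------
    tx_affected = affected_by_class["PATHOGENIC"]
    if tx_affected and expression_affected:
        ov = overlap_summary(tx_affected, expression_affected)
        for g in tx_affected & expression_affected:
            gene_flags.setdefault(g, {})["in_overlap"] = True
        sections["overlap"] = ov
    else:
        sections["overlap"] = {"skipped": True}

    # ---------------- burden ----------------------------------------------
    if config.gene_sets:
        universe = set(gene_flags)
        if genes is not None:
            universe |= {g.gene_id for g in genes}
        affected_sets = {
            f"transcript_{c}": affected_by_class[c] for c in _CLASSES
        }
        affected_sets["expression"] = expression_affected
        burden_block: dict = {}
        for cname, path in sorted(config.gene_sets.items()):
            collection = read_gmt(path, universe=universe)
            per_flag = {}
            for flag, aff in sorted(affected_sets.items()):
                try:
                    summ = summarize_collection(
                        collection, aff, thresholds=config.burden_thresholds
                    )
                except ValueError:
                    continue
                per_flag[flag] = {
                    "fractions": summ.fractions,
                    "effective_sizes": summ.effective_sizes,
                    "mean_fraction": summ.mean_fraction,
                    "n_scored": summ.n_scored,
                    "count_ge_25": summ.count_ge_25,
                    "count_ge_50": summ.count_ge_50,
                    "prop_ge_25": summ.prop_ge_25,
                    "prop_ge_50": summ.prop_ge_50,
                }
            burden_block[cname] = per_flag
        sections["burden"] = burden_block
    else:
        sections["burden"] = {"skipped": True}

    # ---------------- network context -------------------------------------
    if config.networks and expression_affected:
        net_block = {}
        for nname, path in sorted(config.networks.items()):
            graph = network_mod.read_edge_list(path)
            nodes = set(graph.nodes)
            observed_genes = expression_affected & nodes
            if len(observed_genes) < 10:
                net_block[nname] = {"skipped": True, "reason": "too few affected nodes"}
                continue
            sub = network_mod.induced_subgraph(graph, observed_genes)
            observed = network_mod.summarize_network(
                sub,
                method=config.exponent_method,
                with_betweenness=config.network_betweenness,
            )
            null = network_mod.random_null(
                graph,
                k=len(observed_genes),
                n_replicates=config.null_replicates,
                candidate_pool=sorted(nodes),
                seed=config.seed,
                method=config.exponent_method,
                with_betweenness=config.network_betweenness,
            )
            comparison = network_mod.compare_to_null(observed, null)
            net_block[nname] = {
                "n_affected_in_network": len(observed_genes),
                "observed": {
                    "gamma": observed.gamma,
                    "mean_betweenness": observed.mean_betweenness,
                    "edge_density": observed.edge_density,
                    "n_nodes": observed.n_nodes,
                    "n_edges": observed.n_edges,
                },
                "null": {"mean": null.mean, "sd": null.sd, "n_replicates": null.n_replicates,
                         "seed": null.seed},
                "comparison": comparison,
            }
        sections["network"] = net_block
    else:
        sections["network"] = {"skipped": True}

    checksums = {
        str(Path(p).name): _sha256(Path(p))
        for p in config._paths()
        if p is not None
    }
    provenance = {
        "config": {
            k: (str(v) if isinstance(v, Path) else
                {kk: str(vv) for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "input_checksums": checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return AnalysisReport(
        sections=sections,
        gene_flags=gene_flags,
        annotation_rows=annotation_rows,
        provenance=provenance,
    )
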