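"""Fraction-of-affected-genes scoring of gene-set collections.

Pathway and disease gene sets are scored by the fraction of their in-universe
members carrying a flag (transcript-affected or expression-affected); the
collection summary reports the mean fraction and how many sets are affected
for at least 25% / 50% of their genes. Denominators are restricted to the
analysis universe — genes without annotation or expression results cannot be
classified either way and would bias fractions toward zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "BurdenSummary",
    "GeneSet",
    "GeneSetCollection",
    "fraction_affected",
    "overlap_summary",
    "read_gmt",
    "summarize_collection",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: tuple[GeneSet, ...]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = tuple(self.sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate set names in collection")


@dataclass(frozen=True)
class BurdenSummary:
    """Per-collection burden numbers, mirroring the headline structure of a
    pathway/disease coverage analysis."""

    fractions: Mapping[str, float]  # only sets with non-empty effective membership
    effective_sizes: Mapping[str, int]
    mean_fraction: float
    n_scored: int
    count_ge_25: int
    count_ge_50: int

    @property
    def prop_ge_25(self) -> float:
        return self.count_ge_25 / self.n_scored

    @property
    def prop_ge_50(self) -> float:
        return self.count_ge_50 / self.n_scored


def fraction_affected(
    gene_set: GeneSet, affected: frozenset[str] | set[str], universe: frozenset[str] | set[str]
) -> tuple[float | None, int]:
    """``(fraction, effective_size)`` of a set against an affected-gene set.

    Effective members are the set's genes present in the universe; sets with
    no in-universe member return ``(None, 0)`` and are excluded from
    summaries.
    """
    if not universe:
        raise ValueError("empty analysis universe")
    effective = gene_set.members & frozenset(universe)
    if not effective:
        return None, 0
    return len(effective & frozenset(affected)) / len(effective), len(effective)


def summarize_collection(
    collection: GeneSetCollection,
    affected: frozenset[str] | set[str],
    thresholds: tuple[float, float] = (0.25, 0.50),
) -> BurdenSummary:
    """Score every set and summarize; thresholds are inclusive (≥)."""
    lo, hi = thresholds
    fractions: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for gs in collection.sets:
        frac, size = fraction_affected(gs, affected, collection.universe)
        if frac is not None:
            fractions[gs.name] = frac
            sizes[gs.name] = size
    if not fractions:
        raise ValueError("no scorable sets (all outside the universe)")
    vals = list(fractions.values())
    return BurdenSummary(
        fractions=fractions,
        effective_sizes=sizes,
        mean_fraction=sum(vals) / len(vals),
        n_scored=len(vals),
        count_ge_25=sum(v >= lo for v in vals),
        count_ge_50=sum(v >= hi for v in vals),
    )


def overlap_summary(set_a: set[str], set_b: set[str]) -> dict[str, float]:
    """Intersection size with all three candidate percent denominators.

    The headline percentage uses the smaller set; the union and per-set
    denominators are reported alongside since published overlap percentages
    rarely state their base.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    inter = len(set_a & set_b)
    return {
        "intersection": inter,
        "size_a": len(set_a),
        "size_b": len(set_b),
        "percent_of_smaller": 100.0 * inter / min(len(set_a), len(set_b)),
        "percent_of_union": 100.0 * inter / len(set_a | set_b),
        "percent_of_larger": 100.0 * inter / max(len(set_a), len(set_b)),
    }


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] = ()) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members).

    Duplicate members within a set are deduplicated; empty sets are dropped
    with a warning; a duplicated set name is an error.
    """
    sets = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name<TAB>description")
            name, desc, *members = fields
            if name in seen:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            seen.add(name)
            members = frozenset(m for m in members if m)
            if not members:
                warnings.warn(f"{path}: line {lineno}: empty set {name!r} dropped")
                continue
            sets.append(GeneSet(name=name, members=members, description=desc))
    return GeneSetCollection(sets=tuple(sets), universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets:
            fh.write(
                "\t".join([gs.name, gs.description or "na", *sorted(gs.members)]) + "\n"
            )
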