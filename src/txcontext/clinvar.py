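"""Clinical-significance classification and the transcript-affected rule.

A variant record carries one assertion per submitter; records without any
submitter providing manually curated assertion criteria are excluded.
Retained records partition into PATHOGENIC / VUS / BENIGN / EXCLUDED:

* PATHOGENIC — every non-``other`` submission is (likely) pathogenic, with
  at least one such submission and no conflicting classification;
* BENIGN — every non-``other`` submission is (likely) benign and at least
  one submitter used the full ``benign`` label;
* VUS — any ``uncertain`` submission, or submissions conflicting across the
  pathogenic/benign divide;
* EXCLUDED — everything else (including likely_benign-only records).

A gene is *transcript-affected* for a significance class when at least one
variant of that class has two transcripts of the gene with different impact
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2_contingency

from .consequence import ConsequenceCall, ImpactClass, Variant

__all__ = [
    "Significance",
    "SignificanceClass",
    "SubmitterAssertion",
    "VariantAssertionRecord",
    "classify_significance",
    "flag_transcript_affected",
    "proportion_test",
    "read_assertion_table",
    "write_assertion_table",
]


class Significance(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    OTHER = "other"


class SignificanceClass(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    VUS = "VUS"
    BENIGN = "BENIGN"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SubmitterAssertion:
    significance: Significance
    has_assertion_criteria: bool = False


@dataclass
class VariantAssertionRecord:
    variant: Variant
    gene_id: str
    submitters: tuple[SubmitterAssertion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.submitters = tuple(self.submitters)
        if not self.submitters:
            raise ValueError("assertion record without submitters")


_PATH = {Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC}
_BEN = {Significance.BENIGN, Significance.LIKELY_BENIGN}


def classify_significance(record: VariantAssertionRecord) -> SignificanceClass:
    """Map one multi-submitter record to a single significance class."""
    if not record.submitters:
        raise ValueError("assertion record without submitters")
    if not any(s.has_assertion_criteria for s in record.submitters):
        return SignificanceClass.EXCLUDED
    sigs = [s.significance for s in record.submitters if s.significance != Significance.OTHER]
    if not sigs:
        return SignificanceClass.EXCLUDED
    has_path = any(s in _PATH for s in sigs)
    has_ben = any(s in _BEN for s in sigs)
    if any(s == Significance.UNCERTAIN for s in sigs) or (has_path and has_ben):
        return SignificanceClass.VUS
    if has_path and all(s in _PATH for s in sigs):
        return SignificanceClass.PATHOGENIC
    if all(s in _BEN for s in sigs) and any(s == Significance.BENIGN for s in sigs):
        return SignificanceClass.BENIGN
    return SignificanceClass.EXCLUDED


def flag_transcript_affected(
    calls_by_variant: Mapping[Variant, Sequence[ConsequenceCall]],
) -> bool:
    """True iff some variant shows ≥2 distinct impact classes across the
    gene's transcripts.

    ``calls_by_variant`` must already be restricted to variants of the
    significance class under study and to biotype-whitelisted transcripts.
    A gene with no qualifying variants (or only single-transcript evidence)
    is simply not flagged.
    """
    for calls in calls_by_variant.values():
        impacts = {c.impact for c in calls}
        if len(impacts) >= 2:
            return True
    return False


def witness_variants(
    calls_by_variant: Mapping[Variant, Sequence[ConsequenceCall]],
) -> list[Variant]:
    """Variants whose impact class differs between transcripts."""
    return [
        v
        for v, calls in calls_by_variant.items()
        if len({c.impact for c in calls}) >= 2
    ]


def proportion_test(
    affected: Sequence[int], totals: Sequence[int]
) -> tuple[float, float, float]:
    """Pearson chi-squared comparison of affected-gene proportions across
    significance classes.

    Parameters are parallel per-class counts. Returns ``(statistic,
    p_value, effect_size)`` where the effect size is the maximum pairwise
    difference in proportions. No continuity correction is applied.
    """
    if len(affected) != len(totals) or len(totals) < 2:
        raise ValueError("need parallel counts for >= 2 classes")
    if any(a < 0 or t <= 0 or a > t for a, t in zip(affected, totals)):
        raise ValueError("counts must satisfy 0 <= affected <= total, total > 0")
    table = [[a, t - a] for a, t in zip(affected, totals)]
    if any(sum(col) == 0 for col in zip(*table)):
        raise ValueError("a column total of the contingency table is zero")
    props = [a / t for a, t in zip(affected, totals)]
    if len(set(props)) == 1:
        # identical proportions: chi2 = 0 exactly, avoid float fuzz
        return 0.0, 1.0, 0.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    effect = max(props) - min(props)
    return float(stat), float(p), float(effect)


# ---------------------------------------------------------------------------
# assertion-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = (
    "chrom\tpos\tref\talt\tgene_id\tsubmitter_index\tsignificance\tassertion_criteria"
)


def write_assertion_table(
    records: Iterable[VariantAssertionRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(_COLUMNS + "\n")
        for rec in records:
            v = rec.variant
            for i, sub in enumerate(rec.submitters):
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{rec.gene_id}\t{i}\t"
                    f"{sub.significance.value}\t{int(sub.has_assertion_criteria)}\n"
                )


def read_assertion_table(path: str | Path) -> list[VariantAssertionRecord]:
    by_key: dict[tuple, dict] = {}
    order: list[tuple] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected assertion-table header")
        for line in fh:
            chrom, pos, ref, alt, gene_id, idx, sig, crit = line.rstrip("\n").split("\t")
            key = (chrom, int(pos), ref, alt, gene_id)
            if key not in by_key:
                by_key[key] = {"subs": []}
                order.append(key)
            by_key[key]["subs"].append(
                (int(idx), SubmitterAssertion(Significance(sig), bool(int(crit))))
            )
    out = []
    for key in order:
        chrom, pos, ref, alt, gene_id = key
        subs = [s for _, s in sorted(by_key[key]["subs"], key=lambda t: t[0])]
        out.append(
            VariantAssertionRecord(
                variant=Variant(chrom=chrom, pos=pos, ref=ref, alt=alt),
                gene_id=gene_id,
                submitters=tuple(subs),
            )
        )
    return out
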