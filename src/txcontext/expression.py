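"""Cross-tissue ANOVA and the expression-affected gene classifier.

A gene is *expression-affected* when, using its most highly expressed
transcript, (1) its expression summary is at or above the 80th percentile of
genes, (2) the one-way inter-tissue ANOVA has p < 1e-30, and (3) the
inter-tissue mean square is at least 10x the intra-tissue mean square. All
three criteria are conjunctive and are evaluated on log2(TPM+1) values; the
extreme fixed p threshold is the multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "AnovaResult",
    "ExpressionFlag",
    "ExpressionMatrix",
    "Thresholds",
    "anova_one_way",
    "flag_expression_affected",
    "read_expression_tsv",
    "select_top_transcript",
]


@dataclass(frozen=True)
class Thresholds:
    """The classifier's three fixed criteria."""

    percentile_min: float = 80.0
    p_max: float = 1e-30
    variance_ratio_min: float = 10.0


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects one-way decomposition of one transcript's values."""

    F: float
    p_value: float
    ms_between: float
    ms_within: float
    df_between: int
    df_within: int
    degenerate: bool = False

    @property
    def variance_ratio(self) -> float:
        if self.ms_within == 0.0:
            return float("inf") if self.ms_between > 0 else 0.0
        return self.ms_between / self.ms_within


@dataclass(frozen=True)
class ExpressionFlag:
    gene_id: str
    top_transcript: str
    expression_summary: float
    percentile_rank: float
    anova: AnovaResult
    expression_affected: bool


class ExpressionMatrix:
    """Transcript × sample TPM matrix with tissue labels and a gene map."""

    def __init__(
        self,
        values: pd.DataFrame,
        sample_tissue: pd.Series,
        transcript_gene: pd.Series,
    ):
        if not values.columns.equals(sample_tissue.index):
            sample_tissue = sample_tissue.reindex(values.columns)
        if sample_tissue.isna().any():
            raise ValueError("every sample needs a tissue label")
        counts = sample_tissue.value_counts()
        if len(counts) < 2:
            raise ValueError("need >= 2 tissues")
        if (counts < 2).any():
            raise ValueError("every tissue needs >= 2 samples")
        missing = values.index.difference(transcript_gene.index)
        if len(missing):
            raise ValueError(f"transcripts without gene mapping: {list(missing)[:5]}")
        if (values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.values = values
        self.sample_tissue = sample_tissue
        self.transcript_gene = transcript_gene.loc[values.index]
        self._log: pd.DataFrame | None = None

    @property
    def log_values(self) -> pd.DataFrame:
        if self._log is None:
            self._log = np.log2(self.values + 1.0)
        return self._log

    def genes(self) -> list[str]:
        return sorted(self.transcript_gene.unique())


def anova_one_way(groups: dict[str, np.ndarray] | list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA across tissue groups.

    ``ms_between = Σ n_t (x̄_t − x̄)² / (T−1)``,
    ``ms_within = Σ_t Σ_s (x_ts − x̄_t)² / (N−T)``; the p-value is the upper
    tail of F(T−1, N−T). A zero within-group mean square is degenerate:
    p = 0 if any between-group signal remains, else p = 1.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 observations")
    n_total = sum(a.size for a in arrays)
    n_groups = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = n_groups - 1, n_total - n_groups
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        if ms_b > 0.0:
            return AnovaResult(float("inf"), 0.0, ms_b, 0.0, df_b, df_w, degenerate=True)
        return AnovaResult(0.0, 1.0, 0.0, 0.0, df_b, df_w, degenerate=True)
    F = ms_b / ms_w
    p = float(f_dist.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, float(ms_b), float(ms_w), df_b, df_w)


def select_top_transcript(gene_id: str, matrix: ExpressionMatrix) -> str:
    """Transcript maximizing mean log2(TPM+1) across all samples; exact ties
    break to the lexicographically smallest transcript id."""
    tx_ids = matrix.transcript_gene.index[matrix.transcript_gene == gene_id]
    if len(tx_ids) == 0:
        raise KeyError(f"gene {gene_id!r} absent from expression matrix")
    means = matrix.log_values.loc[tx_ids].mean(axis=1)
    best = means.max()
    return sorted(means.index[means == best])[0]


def flag_expression_affected(
    matrix: ExpressionMatrix, thresholds: Thresholds = Thresholds()
) -> dict[str, ExpressionFlag]:
    """Apply the three-criterion classifier to every gene in the matrix."""
    log_vals = matrix.log_values
    tissues = matrix.sample_tissue
    tissue_cols = {t: tissues.index[tissues == t] for t in sorted(tissues.unique())}

    summaries: dict[str, float] = {}
    top_tx: dict[str, str] = {}
    for gene in matrix.genes():
        tx = select_top_transcript(gene, matrix)
        top_tx[gene] = tx
        summaries[gene] = float(log_vals.loc[tx].mean())

    summary_series = pd.Series(summaries)
    # percentile rank of each gene's summary over all genes, in [0, 100]
    ranks = summary_series.rank(pct=True) * 100.0

    flags: dict[str, ExpressionFlag] = {}
    for gene, tx in top_tx.items():
        row = log_vals.loc[tx]
        res = anova_one_way([row[cols].to_numpy() for cols in tissue_cols.values()])
        affected = (
            ranks[gene] >= thresholds.percentile_min
            and res.p_value < thresholds.p_max
            and res.variance_ratio >= thresholds.variance_ratio_min
        )
        flags[gene] = ExpressionFlag(
            gene_id=gene,
            top_transcript=tx,
            expression_summary=summaries[gene],
            percentile_rank=float(ranks[gene]),
            anova=res,
            expression_affected=bool(affected),
        )
    return flags


def read_expression_tsv(
    values_path: str | Path,
    sample_annotation_path: str | Path,
    transcript_gene_path: str | Path,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from its three TSV companions."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_annotation_path, sep="\t", index_col=0)
    tx_gene = pd.read_csv(transcript_gene_path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=values,
        sample_tissue=samples.iloc[:, 0],
        transcript_gene=tx_gene.iloc[:, 0],
    )
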