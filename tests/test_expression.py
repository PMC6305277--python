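"""One-way ANOVA correctness and the three-criterion expression classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txcontext.expression import (
    ExpressionMatrix,
    Thresholds,
    anova_one_way,
    flag_expression_affected,
    read_expression_tsv,
    select_top_transcript,
)
from txcontext.synthetic import dummy_gene_models, simulate_expression


# ------------------------------------------------------------------- ANOVA
def test_two_group_anova_equals_t_test():
    """F = t² and identical p for the equal-variance two-sample case."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(0, 1, size=rng.integers(3, 12))
        b = rng.normal(0.5, 1, size=rng.integers(3, 12))
        res = anova_one_way([a, b])
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(1)
    groups = [rng.normal(m, 1, size=8) for m in (0, 1, 2, 0.5)]
    res = anova_one_way(groups)
    F, p = stats.f_oneway(*groups)
    assert res.F == pytest.approx(F, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)


def test_sum_of_squares_identity():
    """ss_between + ss_within == total ss, to 1e-9 relative, on random data."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        groups = [
            rng.normal(rng.normal(0, 2), rng.uniform(0.5, 2), size=rng.integers(2, 15))
            for _ in range(rng.integers(2, 8))
        ]
        res = anova_one_way(groups)
        allv = np.concatenate(groups)
        total_ss = ((allv - allv.mean()) ** 2).sum()
        recomposed = res.ms_between * res.df_between + res.ms_within * res.df_within
        assert recomposed == pytest.approx(total_ss, rel=1e-9)


def test_degenerate_groups():
    res = anova_one_way([np.zeros(4), np.zeros(4)])
    assert res.degenerate and res.p_value == 1.0
    res = anova_one_way([np.zeros(4), np.full(4, 10.0)])
    assert res.degenerate and res.p_value == 0.0 and res.F == np.inf
    with pytest.raises(ValueError):
        anova_one_way([np.zeros(4)])
    with pytest.raises(ValueError):
        anova_one_way([np.zeros(1), np.zeros(4)])


def test_strong_separation_exceeds_ratio_threshold():
    rng = np.random.default_rng(3)
    a = 0.0 + rng.normal(0, 0.01, 4)
    b = 10.0 + rng.normal(0, 0.01, 4)
    res = anova_one_way([a, b])
    assert res.variance_ratio > 10


def test_scale_invariance_of_variance_ratio():
    rng = np.random.default_rng(4)
    groups = [rng.normal(m, 1, 10) for m in (0, 3, 5)]
    r1 = anova_one_way(groups).variance_ratio
    r2 = anova_one_way([7.5 * g for g in groups]).variance_ratio
    assert r1 == pytest.approx(r2, rel=1e-12)


# -------------------------------------------------------- matrix + selection
def _matrix(values, tissues):
    df = pd.DataFrame(values)
    return ExpressionMatrix(
        values=df,
        sample_tissue=pd.Series(tissues, index=df.columns),
        transcript_gene=pd.Series(
            {tx: tx.split(".")[0] for tx in df.index}, name="gene"
        ),
    )


def test_select_top_transcript_by_mean_and_ties():
    df = pd.DataFrame(
        {
            "s1": [31.0, 1.0, 3.0, 3.0],
            "s2": [31.0, 2.0, 3.0, 3.0],
            "s3": [31.0, 1.5, 3.0, 3.0],
            "s4": [31.0, 1.0, 3.0, 3.0],
        },
        index=["gA.t1", "gA.t2", "gB.t2", "gB.t1"],
    )
    m = _matrix(df, ["x", "x", "y", "y"])
    assert select_top_transcript("gA", m) == "gA.t1"
    assert select_top_transcript("gB", m) == "gB.t1"  # exact tie -> lexicographic
    with pytest.raises(KeyError):
        select_top_transcript("gZ", m)


def test_matrix_invariants():
    df = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g.t1"])
    with pytest.raises(ValueError, match=">= 2 tissues"):
        _matrix(df, ["x", "x"])
    df2 = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["g.t1"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        _matrix(df2, ["x", "x", "y"])
    with pytest.raises(ValueError, match="non-negative"):
        _matrix(pd.DataFrame({"s1": [-1.0, 1], "s2": [1.0, 1], "s3": [1.0, 1], "s4": [1.0, 1]},
                             index=["g.t1", "h.t1"]), ["x", "x", "y", "y"])


# --------------------------------------------------------------- classifier
@pytest.fixture(scope="module")
def planted():
    genes = dummy_gene_models(60, transcripts_per_gene=2)
    values, tissues, tx_gene, truth = simulate_expression(
        genes, n_tissues=8, samples_per_tissue=15, planted_fraction=0.1,
        effect_log2=6.0, sigma=0.5, seed=5,
    )
    matrix = ExpressionMatrix(values, tissues, tx_gene)
    return matrix, truth


def test_planted_tissue_enriched_genes_are_flagged(planted):
    matrix, truth = planted
    flags = flag_expression_affected(matrix)
    planted_ids = set(truth.expression["planted"])
    hits = {g for g, f in flags.items() if f.expression_affected}
    assert planted_ids <= hits or len(planted_ids - hits) <= 1
    # false positives essentially impossible at p < 1e-30
    assert len(hits - planted_ids) == 0


def test_criteria_are_conjunctive(planted):
    matrix, _ = planted
    flags = flag_expression_affected(matrix)
    for f in flags.values():
        expected = (
            f.percentile_rank >= 80
            and f.anova.p_value < 1e-30
            and f.anova.variance_ratio >= 10
        )
        assert f.expression_affected == expected


def test_flat_high_abundance_gene_not_flagged():
    rng = np.random.default_rng(6)
    rows = {f"g{i:02d}.t1": np.exp2(rng.normal(2, 0.5, 20)) for i in range(19)}
    rows["hi.t1"] = np.exp2(rng.normal(12, 0.5, 20))  # high but tissue-flat
    df = pd.DataFrame(rows, index=None).T
    df.columns = [f"s{j}" for j in range(20)]
    m = _matrix(df, ["a"] * 10 + ["b"] * 10)
    flags = flag_expression_affected(m)
    assert flags["hi"].percentile_rank >= 80
    assert not flags["hi"].expression_affected


def test_sample_permutation_invariance(planted):
    matrix, _ = planted
    flags = flag_expression_affected(matrix)
    rng = np.random.default_rng(7)
    perm = rng.permutation(matrix.values.columns)
    permuted = ExpressionMatrix(
        matrix.values[perm], matrix.sample_tissue[perm], matrix.transcript_gene
    )
    flags2 = flag_expression_affected(permuted)
    assert {g: f.expression_affected for g, f in flags.items()} == {
        g: f.expression_affected for g, f in flags2.items()
    }


def test_label_shuffle_destroys_flags(planted):
    """Random tissue labels remove the planted structure (empirical FPR)."""
    matrix, _ = planted
    rng = np.random.default_rng(8)
    shuffled = pd.Series(
        rng.permutation(matrix.sample_tissue.values), index=matrix.sample_tissue.index
    )
    flags = flag_expression_affected(
        ExpressionMatrix(matrix.values, shuffled, matrix.transcript_gene)
    )
    n_flagged = sum(f.expression_affected for f in flags.values())
    assert n_flagged / len(flags) <= 0.01


def test_expression_tsv_round_trip(tmp_path, planted):
    matrix, _ = planted
    matrix.values.to_csv(tmp_path / "e.tsv", sep="\t", index_label="transcript_id")
    matrix.sample_tissue.to_frame().to_csv(tmp_path / "s.tsv", sep="\t", index_label="sample_id")
    matrix.transcript_gene.to_frame().to_csv(tmp_path / "g.tsv", sep="\t", index_label="transcript_id")
    back = read_expression_tsv(tmp_path / "e.tsv", tmp_path / "s.tsv", tmp_path / "g.tsv")
    flags_a = flag_expression_affected(matrix)
    flags_b = flag_expression_affected(back)
    assert {g: f.expression_affected for g, f in flags_a.items()} == {
        g: f.expression_affected for g, f in flags_b.items()
    }
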