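import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from diapop.splice import (
    Contrast,
    classify_genes,
    compute_psi,
    diff_event_usage,
    diff_exon_usage,
    diff_gene_expression,
    enumerate_comparisons,
    filter_events,
    filter_low_expression,
    pca_variance,
    residual_exon_expression,
    simes_p,
    tmm_normalize,
)
from diapop.tables import CountTable, EventRecord


def _design(groups):
    """groups: dict (trajectory, day) -> list of sample ids."""
    rows = []
    for (traj, day), samples in groups.items():
        for s in samples:
            rows.append({"sample_id": s, "trajectory": traj, "day": day, "tissue": "head"})
    return pd.DataFrame(rows)


def _count_table(counts: np.ndarray, genes, samples=None, level="exon"):
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    ids = [f"f{i}" for i in range(counts.shape[0])] if level == "exon" else list(genes)
    return CountTable(
        pd.DataFrame(counts, index=ids, columns=samples),
        pd.Series(list(genes), index=ids),
        level,
    )


# ---------------------------------------------------------------------------
# contrast design


@pytest.mark.parametrize(
    "dia, dire, expected",
    [
        ((0, 3, 6, 24, 114, 144, 155), (0, 3, 6), 15),
        ((0,), (0,), 1),
        ((0, 3), (0, 3), 3),
    ],
    ids=["full-design", "day0-only", "dedup-reference-stepwise"],
)
def test_enumerate_comparisons_counts(dia, dire, expected):
    cs = enumerate_comparisons(dia, dire)
    assert len(cs) == expected
    assert len({c.pair for c in cs}) == expected  # no duplicate unordered pairs


def test_enumerate_comparisons_structure():
    cs = enumerate_comparisons((0, 3, 6, 24, 114, 144, 155), (0, 3, 6))
    kinds = [c.kind for c in cs]
    assert kinds.count("cross_day0") == 1
    assert kinds.count("reference") == 8  # 6 diapause + 2 direct
    assert kinds.count("stepwise") == 6  # adjacent pairs minus the two day-0 dups
    assert cs[0].kind == "cross_day0"


def test_enumerate_comparisons_rejects_unsorted_or_empty():
    with pytest.raises(ValueError):
        enumerate_comparisons((3, 0), (0,))
    with pytest.raises(ValueError):
        enumerate_comparisons((), (0,))


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_libraries_give_unit_factors(rng):
    counts = rng.poisson(100, size=(500, 1))
    t = _count_table(np.hstack([counts, counts]), ["g"] * 500)
    n = tmm_normalize(t)
    np.testing.assert_allclose(n.norm_factors.to_numpy(), [1.0, 1.0], atol=1e-12)


def test_tmm_pure_depth_difference_absorbed_by_cpm(rng):
    counts = rng.poisson(100, size=(500, 1))
    t = _count_table(np.hstack([counts, counts * 2]), ["g"] * 500)
    n = tmm_normalize(t)
    np.testing.assert_allclose(n.norm_factors.to_numpy(), [1.0, 1.0], atol=1e-12)


def test_tmm_matches_independent_reference_implementation():
    """Factors agree with edgeR::calcNormFactors on a seeded matrix where
    one sample has 20% of features up 8-fold (reference values computed
    with edgeR 4.0.16 and frozen)."""
    rng = np.random.default_rng(2024)
    base = np.exp(rng.normal(np.log(100), 1.2, size=800))
    counts = np.vstack([rng.poisson(base * f) for f in (1.0, 1.0, 2.0, 0.7, 1.3, 1.0)]).T
    up = rng.random(800) < 0.2
    counts[up, 2] = rng.poisson(base[up] * 2.0 * 8.0)
    t = _count_table(counts, ["g"] * 800)
    n = tmm_normalize(t)
    reference = np.array(
        [1.1481004086, 1.1455965224, 0.5087520120, 1.1417893041, 1.1463389097, 1.1417822783]
    )
    np.testing.assert_allclose(n.norm_factors.to_numpy(), reference, atol=1e-6)


# ---------------------------------------------------------------------------
# residual exon expression


def test_residuals_center_within_gene():
    values = pd.DataFrame({"s1": [5.0, 3.0], "s2": [2.0, 2.0]}, index=["f0", "f1"])
    from diapop.splice import NormalizedMatrix

    norm = NormalizedMatrix(values, pd.Series([1.0, 1.0], index=["s1", "s2"]), pd.Series([1, 1], index=["s1", "s2"]))
    res = residual_exon_expression(norm, pd.Series(["g", "g"], index=["f0", "f1"]))
    np.testing.assert_allclose(res["s1"], [1.0, -1.0])
    np.testing.assert_allclose(res["s2"], [0.0, 0.0])


@given(st.integers(0, 2**31 - 1))
def test_residual_properties(seed):
    rng = np.random.default_rng(seed)
    n_exon = 12
    genes = pd.Series(
        [f"g{i}" for i in rng.integers(0, 4, n_exon)], index=[f"f{i}" for i in range(n_exon)]
    )
    values = pd.DataFrame(
        rng.normal(size=(n_exon, 3)), index=genes.index, columns=["s1", "s2", "s3"]
    )
    from diapop.splice import NormalizedMatrix

    norm = NormalizedMatrix(values, pd.Series(1.0, index=values.columns), pd.Series(1, index=values.columns))
    res = residual_exon_expression(norm, genes)
    sums = res.groupby(genes.to_numpy()).sum()
    np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-9)
    # shift invariance: adding a constant to all exons of one gene, one sample
    shifted = values.copy()
    shifted.loc[genes == genes.iloc[0], "s1"] += 7.3
    norm2 = NormalizedMatrix(shifted, norm.norm_factors, norm.effective_lib_sizes)
    res2 = residual_exon_expression(norm2, genes)
    np.testing.assert_allclose(res.to_numpy(), res2.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# low-expression filter


def test_filter_low_expression_rules():
    design = _design({("diapause", 0): ["a1"], ("direct", 0): ["b1", "b2"]})
    # equal library sizes of 1e6 -> CPM cutoff = 10, count threshold = 10
    filler = np.array([[1_000_000 - 15, 1_000_000 - 1000, 1_000_000]])
    rows = np.array(
        [
            [0, 0, 0],  # all zero -> dropped
            [1000, 1000, 0],  # clearly kept
            [15, 0, 0],  # boundary: CPM 15 >= 10 in k=1 sample, total 15 -> kept
            [14, 0, 0],  # total 14 < 15 -> dropped
        ]
    )
    counts = np.vstack([rows, filler - rows.sum(axis=0, keepdims=True)])
    t = _count_table(counts, [f"g{i}" for i in range(len(counts))], samples=["a1", "b1", "b2"])
    keep = filter_low_expression(t, design)
    assert keep.tolist()[:4] == [False, True, True, False]


# ---------------------------------------------------------------------------
# Simes aggregation and the exon test


def test_simes_worked_example():
    assert simes_p([0.04, 0.015, 0.02]) == pytest.approx(0.03, abs=1e-12)


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
def test_simes_bounds(ps):
    s = simes_p(ps)
    assert min(ps) - 1e-12 <= s <= min(1.0, len(ps) * min(ps)) + 1e-12
    if len(ps) == 1:
        assert s == pytest.approx(min(ps[0], 1.0))


def _two_group_design(n=3):
    return _design(
        {
            ("diapause", 0): [f"a{i}" for i in range(n)],
            ("diapause", 3): [f"b{i}" for i in range(n)],
        }
    )


CONTRAST = Contrast(("diapause", 0), ("diapause", 3), "reference")


def test_diff_exon_usage_detects_planted_share_shift(rng):
    design = _two_group_design()
    n_genes = 50
    counts = []
    genes = []
    for g in range(n_genes):
        w = np.array([0.5, 0.5])
        w_b = np.array([0.8, 0.2]) if g == 0 else w  # planted shift in gene 0
        rows = np.zeros((2, 6), dtype=int)
        for j in range(6):
            weights = w_b if (j >= 3 and g == 0) else w
            rows[:, j] = rng.multinomial(4000, weights)
        counts.append(rows)
        genes += [f"g{g}"] * 2
    t = _count_table(np.vstack(counts), genes, samples=["a0", "a1", "a2", "b0", "b1", "b2"])
    gene_res, exon_res = diff_exon_usage(t, design, CONTRAST)
    assert bool(gene_res.loc["g0", "significant"])
    assert gene_res["significant"].iloc[1:].sum() == 0
    # Simes p bounded by the exon p-values of the gene
    sub = exon_res[exon_res["gene_id"] == "g0"]["p_value"]
    assert gene_res.loc["g0", "simes_p"] >= sub.min() - 1e-12


def test_diff_exon_usage_skips_single_exon_genes():
    design = _two_group_design()
    counts = np.tile([[100, 100, 100, 100, 100, 100]], (3, 1))
    t = _count_table(counts, ["g0", "g1", "g1"], samples=["a0", "a1", "a2", "b0", "b1", "b2"])
    gene_res, _ = diff_exon_usage(t, design, CONTRAST)
    assert "g0" not in gene_res.index or not bool(gene_res.loc["g0", "significant"])
    assert not gene_res.loc["g1", "significant"]


# ---------------------------------------------------------------------------
# PSI and the event test


@pytest.mark.parametrize(
    "inc, skip, il, sl, expected",
    [(10, 10, 1, 1, 0.5), (7, 0, 2, 1, 1.0), (18, 2, 2, 1, 9 / 11)],
)
def test_compute_psi_values(inc, skip, il, sl, expected):
    assert compute_psi(inc, skip, il, sl) == pytest.approx(expected)


def test_compute_psi_missing_and_errors():
    assert np.isnan(compute_psi(0, 0, 2, 1))
    with pytest.raises(ValueError):
        compute_psi(1, 1, 0, 1)


@given(st.integers(1, 1000), st.integers(0, 1000), st.integers(1, 10))
def test_compute_psi_scale_invariance(inc, skip, factor):
    a = compute_psi(inc, skip, 2, 1)
    b = compute_psi(inc * factor, skip * factor, 2, 1)
    assert a == pytest.approx(b)


def _event(inc, skip, samples):
    return EventRecord(
        "e1", "g1", "SE", 2, 1, pd.Series(inc, index=samples), pd.Series(skip, index=samples)
    )


def test_filter_events_read_support_rule():
    samples = ["a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3"]
    design = _design({("diapause", 0): samples[:4], ("diapause", 3): samples[4:]})
    # group A has only 2 supporting samples -> fails
    ev = _event([5, 6, 0, 2, 10, 10, 10, 10], [0, 1, 0, 1, 10, 10, 10, 10], samples)
    assert filter_events([ev], design, CONTRAST) == []
    ev2 = _event([10] * 8, [10] * 8, samples)
    assert filter_events([ev2], design, CONTRAST) == [ev2]
    ev3 = _event([0] * 8, [0] * 8, samples)
    assert filter_events([ev3], design, CONTRAST) == []


def test_diff_event_usage_null_and_planted_and_floor():
    samples = ["a0", "a1", "a2", "b0", "b1", "b2"]
    design = _two_group_design()
    # identical groups: delta PSI 0, not significant
    ev_null = _event([50] * 6, [50] * 6, samples)
    res, calls = diff_event_usage([ev_null], design, CONTRAST)
    assert res["delta_psi"].iloc[0] == pytest.approx(0.0)
    assert not calls.loc["g1"]
    # planted large shift with deep counts, n=3/group: detected
    ev_eff = _event([200, 210, 190, 520, 500, 510], [300, 290, 310, 100, 110, 90], samples)
    res, calls = diff_event_usage([ev_eff], design, CONTRAST)
    assert bool(calls.loc["g1"])
    # tiny delta PSI with enormous counts: p ~ 0 but fails the 0.05 floor
    ev_tiny = _event([100000, 100000, 100000, 104000, 104000, 104000], [100000] * 3 + [96000] * 3, samples)
    res, calls = diff_event_usage([ev_tiny], design, CONTRAST)
    assert res["adjusted_p"].iloc[0] < 0.01
    assert abs(res["delta_psi"].iloc[0]) < 0.05
    assert not bool(calls.loc["g1"])


# ---------------------------------------------------------------------------
# whole-gene expression test


def test_diff_gene_expression_identical_groups_and_planted_fold_change(rng):
    design = _two_group_design()
    n = 300
    base = rng.lognormal(np.log(200), 0.5, n)
    counts = rng.poisson(np.tile(base[:, None], (1, 6))).astype(int)
    # plant a 4-fold change in gene 0 with deep counts
    counts[0, :3] = rng.poisson(2000, 3)
    counts[0, 3:] = rng.poisson(8000, 3)
    t = _count_table(counts, [f"g{i}" for i in range(n)], samples=["a0", "a1", "a2", "b0", "b1", "b2"], level="gene")
    res = diff_gene_expression(t, design, CONTRAST)
    assert bool(res.iloc[0]["significant"])
    assert res.iloc[0]["log2_fc"] == pytest.approx(2.0, abs=0.3)
    assert (res["adjusted_p"].iloc[1:] > 0.5).mean() > 0.9


# ---------------------------------------------------------------------------
# classification


def _calls(sig_labels, contrasts, genes=("gene1",)):
    df = pd.DataFrame(False, index=list(genes), columns=[c.label for c in contrasts])
    for lab in sig_labels:
        df.loc["gene1", lab] = True
    return df


def test_classify_genes_categories():
    cs = enumerate_comparisons((0, 3, 6, 24), (0, 3, 6))
    dia = Contrast(("diapause", 0), ("diapause", 24), "reference").label
    dia2 = Contrast(("diapause", 0), ("diapause", 3), "reference").label
    dire = Contrast(("direct", 0), ("direct", 3), "reference").label
    cross = Contrast(("diapause", 0), ("direct", 0), "cross_day0").label
    assert classify_genes(_calls([dia], cs), cs).loc["gene1"] == "Diap"
    assert classify_genes(_calls([dia2, dire], cs), cs).loc["gene1"] == "Both"
    assert classify_genes(_calls([dire], cs), cs).loc["gene1"] == "Dir"
    assert classify_genes(_calls([], cs), cs).loc["gene1"] == "None"
    # significance only in the cross-trajectory day-0 contrast is not
    # change through a trajectory
    assert classify_genes(_calls([cross], cs), cs).loc["gene1"] == "None"


def test_classify_genes_order_invariant_and_missing_contrast_error():
    cs = enumerate_comparisons((0, 3), (0, 3))
    calls = _calls([cs[1].label], cs)
    a = classify_genes(calls, cs)
    b = classify_genes(calls, list(reversed(cs)))
    pd.testing.assert_series_equal(a, b)
    with pytest.raises(ValueError, match="missing"):
        classify_genes(calls.drop(columns=[cs[1].label]), cs)


# ---------------------------------------------------------------------------
# PCA


def test_pca_variance_fractions(rng):
    direction = rng.normal(size=8)
    weights = rng.normal(size=20)
    mat = pd.DataFrame(np.outer(weights, direction))
    scores, frac = pca_variance(mat, top_n=None)
    assert frac[0] == pytest.approx(1.0, abs=1e-9)
    noisy = pd.DataFrame(rng.normal(size=(30, 8)))
    _, frac2 = pca_variance(noisy)
    assert frac2.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_top_n_and_missing_handling(rng):
    mat = pd.DataFrame(rng.normal(size=(5, 6)) * np.array([[3.0], [2.0], [1.0], [0.1], [0.1]]))
    mat.iloc[4, 0] = np.nan
    scores, _ = pca_variance(mat, top_n=2, complete_only=True)
    assert scores.shape == (6, 6 if 6 < 2 else min(2, 6))
    with pytest.raises(ValueError):
        pca_variance(pd.DataFrame(np.full((3, 4), np.nan)))
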