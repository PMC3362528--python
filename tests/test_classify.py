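"""Unit tests for the dual-stimulus classification calculus."""

import numpy as np
import pandas as pd
import pytest

from naksense import (
    SensitiveSet,
    ca_partition,
    call_differential,
    category_summary,
    concordant_sensitive,
    fixture_annotation,
    fold_correlation,
    sensitive_sets_from_fixture,
    top_table,
    ubiquitous_set,
)
from naksense import load_fixture


def _de_rows(rows, cell="hela", ca="plus", treatment="ouabain"):
    """rows: list of (gene, fold, p, q)."""
    return pd.DataFrame({
        "gene": [r[0] for r in rows],
        "cell_type": cell,
        "calcium": ca,
        "treatment": treatment,
        "fold": [r[1] for r in rows],
        "p": [r[2] for r in rows],
        "q": [r[3] for r in rows],
    })


def _sset(genes_dirs, cell="hela", ca="plus", fold=2.0):
    table = pd.DataFrame({
        "gene": [g for g, _ in genes_dirs],
        "direction": [d for _, d in genes_dirs],
        "ouabain_fold": [fold if d == "up" else -fold for _, d in genes_dirs],
        "kfree_fold": [fold * 1.5 if d == "up" else -fold * 1.5
                       for _, d in genes_dirs],
    })
    return SensitiveSet(cell_type=cell, calcium=ca, table=table)


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------

def test_call_differential_boundaries():
    rows = _de_rows([
        ("in_exact", 1.20, 0.01, 0.049),    # at both boundaries: in
        ("in_down", -1.5, 0.001, 0.01),
        ("out_fold", 1.19, 0.001, 0.001),   # below fold threshold
        ("out_sig", -3.0, 0.2, 0.3),        # not significant
        ("out_alpha", 2.0, 0.01, 0.05),     # q == alpha is not < alpha
    ])
    calls = call_differential(rows)
    assert set(calls["gene"]) == {"in_exact", "in_down"}
    assert dict(zip(calls["gene"], calls["direction"])) == {
        "in_exact": "up", "in_down": "down"}


def test_call_differential_float_round_trip_threshold():
    # a fold that is one ulp short of the threshold after a log2 round
    # trip must still be called, thanks to the relative epsilon slack
    fold = float(np.nextafter(1.2, 0.0))
    assert fold < 1.2
    calls = call_differential(_de_rows([("g", fold, 0.001, 0.001)]))
    assert len(calls) == 1
    # but a materially smaller fold is still excluded
    assert len(call_differential(_de_rows([("g", 1.1999, 0.001, 0.001)]))) == 0


def test_call_differential_raw_p_option():
    rows = _de_rows([("g", 2.0, 0.01, 0.2)])
    assert len(call_differential(rows, use_adjusted=True)) == 0
    assert len(call_differential(rows, use_adjusted=False)) == 1


def test_call_differential_monotone_in_threshold():
    rows = _de_rows([("a", 1.3, 0.001, 0.001), ("b", 2.5, 0.001, 0.001)])
    loose = set(call_differential(rows, threshold=1.2)["gene"])
    strict = set(call_differential(rows, threshold=2.0)["gene"])
    assert strict <= loose
    assert strict == {"b"}


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def test_concordant_sensitive_intersection_and_discordance():
    ouabain = call_differential(_de_rows(
        [("a", 2.0, 0.001, 0.001), ("b", -2.0, 0.001, 0.001),
         ("c", 1.5, 0.001, 0.001)]))
    kfree = call_differential(_de_rows(
        [("a", 3.0, 0.001, 0.001), ("b", 2.0, 0.001, 0.001),
         ("d", 1.5, 0.001, 0.001)], treatment="kfree"))
    sset = concordant_sensitive(ouabain, kfree)
    assert sset.genes == {"a"}          # b flips sign, c/d single-stimulus
    assert sset.discordant == 1
    row = sset.table.iloc[0]
    assert row["ouabain_fold"] == 2.0 and row["kfree_fold"] == 3.0
    # symmetric in its arguments
    mirrored = concordant_sensitive(kfree, ouabain)
    assert mirrored.genes == sset.genes
    assert mirrored.discordant == sset.discordant


def test_concordant_sensitive_rejects_mixed_contexts():
    a = call_differential(_de_rows([("a", 2.0, 0.001, 0.001)], cell="hela"))
    b = call_differential(_de_rows([("a", 2.0, 0.001, 0.001)], cell="huvec",
                                   treatment="kfree"))
    with pytest.raises(ValueError, match="different contexts"):
        concordant_sensitive(a, b)


# ---------------------------------------------------------------------------
# Ubiquity
# ---------------------------------------------------------------------------

def test_ubiquitous_set_intersection_and_direction():
    sets = [
        _sset([("a", "up"), ("b", "down"), ("c", "up")], cell="hela"),
        _sset([("a", "up"), ("b", "down"), ("d", "up")], cell="huvec"),
        _sset([("a", "up"), ("b", "up")], cell="rvsmc"),
    ]
    ubiq = ubiquitous_set(sets)
    # b is in all three but flips direction in rvsmc; c/d miss a cell type
    assert ubiq["gene"].tolist() == ["a"]
    assert set(ubiq.columns) >= {"hela_ouabain", "huvec_kfree",
                                 "rvsmc_ouabain"}


def test_ubiquitous_set_validation():
    with pytest.raises(ValueError, match=">= 2"):
        ubiquitous_set([_sset([("a", "up")])])
    with pytest.raises(ValueError, match="calcium"):
        ubiquitous_set([_sset([("a", "up")], cell="hela", ca="plus"),
                        _sset([("a", "up")], cell="huvec", ca="minus")])
    with pytest.raises(ValueError, match="duplicate cell types"):
        ubiquitous_set([_sset([("a", "up")]), _sset([("a", "up")])])


def test_ubiquitous_subset_of_each_sensitive_set():
    sets = sensitive_sets_from_fixture("table3")
    ubiq = set(ubiquitous_set(sets)["gene"])
    for s in sets:
        assert ubiq <= s.genes


# ---------------------------------------------------------------------------
# Calcium partition
# ---------------------------------------------------------------------------

def test_ca_partition_three_way_split():
    plus = _sset([("a", "up"), ("b", "up")], ca="plus")
    minus = _sset([("b", "down"), ("c", "up")], ca="minus")
    part = ca_partition(plus, minus)
    assert part.ca_containing_only == {"a"}
    assert part.both_conditions == {"b"}
    assert part.ca_depleted_only == {"c"}
    assert part.direction_concordant == {"b": False}
    assert part.label_of() == {"a": "ca_containing_only",
                               "b": "both_conditions",
                               "c": "ca_depleted_only"}


def test_ca_partition_is_exhaustive_and_exclusive(rng):
    genes = [f"g{i}" for i in range(30)]
    plus_genes = [(g, "up") for g in genes if rng.random() < 0.5]
    minus_genes = [(g, "up") for g in genes if rng.random() < 0.5]
    plus = _sset(plus_genes or [("x", "up")], ca="plus")
    minus = _sset(minus_genes or [("y", "up")], ca="minus")
    part = ca_partition(plus, minus)
    union = part.ca_containing_only | part.both_conditions | part.ca_depleted_only
    assert union == plus.genes | minus.genes
    assert not (part.ca_containing_only & part.both_conditions)
    assert not (part.ca_containing_only & part.ca_depleted_only)
    assert not (part.both_conditions & part.ca_depleted_only)


def test_ca_partition_validation():
    with pytest.raises(ValueError, match="one set per calcium"):
        ca_partition(_sset([("a", "up")], ca="plus"),
                     _sset([("a", "up")], ca="plus"))
    with pytest.raises(ValueError, match="scope mismatch"):
        ca_partition(_sset([("a", "up")], cell="hela", ca="plus"),
                     _sset([("a", "up")], cell="huvec", ca="minus"))


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def test_fold_correlation_perfect_on_exact_scaling():
    table = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "direction": ["up", "up", "down", "up"],
        "ouabain_fold": [2.0, 4.0, -2.0, 1.5],
        "kfree_fold": [4.0, 16.0, -4.0, 2.25],  # log2 kfree = 2 × log2 ouabain
    })
    sset = SensitiveSet("hela", "plus", table)
    report = fold_correlation(sset)
    assert report.r == pytest.approx(1.0)
    assert report.r_squared == pytest.approx(1.0)
    assert report.positive


def test_fold_correlation_detects_anticorrelation():
    table = pd.DataFrame({
        "gene": ["a", "b", "c"],
        "direction": ["up", "up", "up"],
        "ouabain_fold": [1.5, 2.0, 4.0],
        "kfree_fold": [4.0, 2.0, 1.5],
    })
    report = fold_correlation(SensitiveSet("hela", "plus", table))
    assert report.r < 0
    assert not report.positive


def test_fold_correlation_validation():
    small = _sset([("a", "up"), ("b", "up")])
    with pytest.raises(ValueError, match="at least 3"):
        fold_correlation(small)
    flat = _sset([("a", "up"), ("b", "up"), ("c", "up")])
    with pytest.raises(ValueError, match="zero variance"):
        fold_correlation(flat)


# ---------------------------------------------------------------------------
# Category summaries and top tables
# ---------------------------------------------------------------------------

def test_category_summary_unannotated_to_other_and_rounding():
    summary = category_summary(["a", "b", "c"], {"a": "t", "b": "d"})
    assert summary.counts == {"t": 1, "d": 1, "f": 0, "i": 0, "o": 1}
    # 100/3 = 33.33 → 33 (half-up rounding)
    assert summary.percentages["t"] == 33
    assert not summary.empty


def test_category_summary_empty_flag():
    summary = category_summary([], {})
    assert summary.empty
    assert set(summary.counts.values()) == {0}


def test_top_table_ranks_by_kfree_magnitude():
    rows = pd.DataFrame({
        "gene": ["weak", "big_down", "big_up"],
        "ouabain_fold": [2.0, -3.0, 5.0],
        "kfree_fold": [3.0, -8.0, 6.0],
    })
    top = top_table(rows, min_abs_fold=4.0)
    assert top["gene"].tolist() == ["big_down", "big_up"]
    assert top_table(rows, min_abs_fold=1e9).empty
    with pytest.raises(ValueError, match="needs columns"):
        top_table(pd.DataFrame({"gene": []}))


# ---------------------------------------------------------------------------
# Fixture adapters
# ---------------------------------------------------------------------------

def test_sensitive_sets_from_fixture_shape():
    sets = sensitive_sets_from_fixture("table3")
    assert {s.cell_type for s in sets} == {"hela", "huvec", "rvsmc"}
    assert all(len(s) == 80 for s in sets)
    with pytest.raises(ValueError, match="ubiquitous-gene table"):
        sensitive_sets_from_fixture("table2")


def test_fixture_annotation_codes():
    ann = fixture_annotation("table3")
    assert len(ann) == 80
    assert set(ann.values()) <= {"t", "d", "f", "i", "o"}
    with pytest.raises(ValueError, match="category"):
        fixture_annotation("table2")


def test_fixture_correlation_is_strongly_positive():
    sets = sensitive_sets_from_fixture("table3")
    for s in sets:
        report = fold_correlation(s)
        assert report.n_genes == 80
        assert report.r > 0.5


def test_fixture_top_table_extremes():
    fx = load_fixture("table4")
    top = top_table(fx, min_abs_fold=4.0)
    assert top["kfree_fold"].min() == pytest.approx(-7.96)
    assert len(top) == len(fx)
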