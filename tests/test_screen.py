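"""Switch screen, Fisher enrichment, and heat-map leaf ordering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescreen.screen import (
    PsiMatrix,
    classify_switch,
    cluster_order,
    compute_shift,
    enrichment_test,
    fisher_exact_2x2,
    qc_filter,
    screen_matrix,
)
from splicescreen.synth import SimConfig, simulate_panel


class TestShift:
    @pytest.mark.parametrize(
        "brain,others,expected",
        [
            (90.0, [20.0, 30.0], 60.0),
            (50.0, [50.0, 50.0], 0.0),
            (90.0, [20.0, 50.0], 40.0),  # nearest tissue governs
            (10.0, [95.0, 70.0, 80.0], 60.0),
        ],
    )
    def test_min_abs_difference_to_reference(self, brain, others, expected):
        row = pd.Series({"brain": brain, **{f"t{i}": v for i, v in enumerate(others)}})
        shift = compute_shift(row, "brain", [f"t{i}" for i in range(len(others))])
        assert shift == pytest.approx(expected)

    def test_missing_comparator_gives_undefined_shift(self):
        row = pd.Series({"brain": 90.0, "kidney": np.nan, "liver": 10.0})
        assert compute_shift(row, "brain", ["kidney", "liver"]) is None

    @pytest.mark.parametrize("shift,threshold,expected", [
        (60.0, 50.0, True),
        (50.0, 50.0, False),  # strict inequality at the boundary
        (50.0 + 1e-9, 50.0, True),
        (5.0, 0.0, True),
    ])
    def test_switch_threshold_is_strict(self, shift, threshold, expected):
        assert classify_switch(shift, threshold) is expected


class TestQcFilter:
    def test_row_missing_one_tissue_dropped(self, small_matrix):
        out = qc_filter(small_matrix)
        assert list(out.values.index) == ["a", "b", "c"]

    def test_fully_populated_matrix_unchanged(self, small_matrix):
        full = PsiMatrix(small_matrix.values.dropna())
        out = qc_filter(full)
        pd.testing.assert_frame_equal(out.values, full.values)

    def test_survivor_count_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, size=(200, 4))
        mask = rng.random(values.shape) < 0.1
        values[mask] = np.nan
        df = pd.DataFrame(values, index=[f"a{i}" for i in range(200)],
                          columns=list("wxyz"))
        expected = sum(
            all(not math.isnan(v) for v in df.loc[i]) for i in df.index
        )
        assert qc_filter(PsiMatrix(df)).values.shape[0] == expected


class TestScreenMatrix:
    def test_incomplete_rows_never_counted(self, small_matrix):
        calls = {c.ase_id: c for c in screen_matrix(small_matrix)}
        assert not calls["d"].complete
        assert calls["d"].shift is None and not calls["d"].is_switch

    def test_switch_calls(self, small_matrix):
        calls = {c.ase_id: c for c in screen_matrix(small_matrix)}
        assert calls["a"].is_switch and calls["a"].shift == pytest.approx(60.0)
        assert calls["a"].direction == 1
        assert not calls["b"].is_switch
        assert calls["c"].shift == pytest.approx(65.0) and calls["c"].direction == -1

    def test_threshold_monotonicity(self):
        panel = simulate_panel(SimConfig(n_ases=150, seed=11))
        m = panel.psi["mouse"]
        sets = []
        for thr in (30.0, 50.0, 70.0):
            calls = screen_matrix(m, threshold=thr)
            sets.append({c.ase_id for c in calls if c.is_switch})
        assert sets[2] <= sets[1] <= sets[0]

    def test_row_permutation_changes_no_call(self):
        panel = simulate_panel(SimConfig(n_ases=80, seed=13))
        m = panel.psi["mouse"]
        perm = np.random.default_rng(0).permutation(m.values.shape[0])
        shuffled = PsiMatrix(m.values.iloc[perm].copy(), m.qc.iloc[perm].copy())
        base = {c.ase_id: (c.shift, c.is_switch) for c in screen_matrix(m)}
        after = {c.ase_id: (c.shift, c.is_switch) for c in screen_matrix(shuffled)}
        assert base == after


class TestFisherExact:
    def test_odds_ratio_from_screen_counts(self):
        # 78/93 switch cassettes vs 482/716 non-switch cassettes
        odds, p = fisher_exact_2x2([[78, 15], [482, 234]])
        assert odds == pytest.approx((78 * 234) / (15 * 482), rel=1e-12)
        assert odds == pytest.approx(2.52, abs=0.01)
        assert 0 < p < 1e-3

    def test_no_association_gives_p_one(self):
        _, p = fisher_exact_2x2([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0)

    def test_degenerate_margin(self):
        odds, p = fisher_exact_2x2([[0, 0], [5, 7]])
        assert odds is None and p == 1.0

    def test_matches_scipy_on_all_small_tables(self):
        """Dual route: enumeration p equals scipy's Fisher exact for every
        2x2 table with total <= 15 (the acceptance suite extends to 30)."""
        total_checked = 0
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        ours_odds, ours_p = fisher_exact_2x2([[a, b], [c, d]])
                        ref = scipy.stats.fisher_exact([[a, b], [c, d]])
                        assert ours_p == pytest.approx(ref.pvalue, abs=1e-10), (a, b, c, d)
                        total_checked += 1
        assert total_checked == sum(
            math.comb(n + 3, 3) for n in range(1, 16)
        )

    @pytest.mark.parametrize("alt", ["greater", "less"])
    def test_one_sided_matches_scipy(self, alt):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            _, p = fisher_exact_2x2([[a, b], [c, d]], alternative=alt)
            ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alt)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestEnrichment:
    def test_counts_built_from_complete_calls_only(self, small_matrix):
        calls = screen_matrix(small_matrix)
        assays = pd.DataFrame({
            "ase_id": ["a", "b", "c", "d"],
            "event_type": ["cassette", "alt5", "cassette", "cassette"],
        })
        res = enrichment_test(calls, assays)
        # d is incomplete and excluded; a and c switch (both cassette), b not
        assert res.table == ((2, 0), (0, 1))
        total = sum(sum(r) for r in res.table)
        assert total == 3

    def test_requires_both_switch_and_nonswitch(self, small_matrix):
        calls = [c for c in screen_matrix(small_matrix) if c.is_switch]
        assays = pd.DataFrame({"ase_id": ["a", "c"], "event_type": ["cassette"] * 2})
        with pytest.raises(ValueError):
            enrichment_test(calls, assays)


def _naive_average_linkage_order(X: np.ndarray) -> list[int]:
    """Single-pass agglomeration with average linkage; left child is the
    older (smaller-id) cluster, matching dendrogram leaf-order conventions."""
    clusters = {i: [i] for i in range(len(X))}
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                np.linalg.norm(X[p] - X[q])
                for p in clusters[i] for q in clusters[j]
            ])
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return next(iter(clusters.values()))


class TestClusterOrder:
    def test_identical_columns_adjacent(self):
        df = pd.DataFrame({
            "brain": [90.0, 10.0, 50.0], "kidney": [20.0, 80.0, 50.0],
            "liver2": [20.0, 80.0, 50.0], "liver": [25.0, 75.0, 55.0],
        }, index=["a", "b", "c"])
        order = cluster_order(PsiMatrix(df), axis="columns")
        cols = [df.columns[i] for i in order]
        assert abs(cols.index("kidney") - cols.index("liver2")) == 1

    def test_singleton_matrix(self):
        df = pd.DataFrame({"x": [10.0], "y": [20.0]}, index=["a"])
        assert cluster_order(PsiMatrix(df)) == [0]

    def test_missing_values_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            cluster_order(small_matrix)

    def test_leaf_order_matches_naive_agglomeration(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            X = rng.uniform(0, 100, size=(5, 3))
            df = pd.DataFrame(X, index=list("abcde"), columns=["t1", "t2", "t3"])
            order = cluster_order(PsiMatrix(df))
            assert order == _naive_average_linkage_order(X)
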