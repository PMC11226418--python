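"""OLS scaling fits, dendrograms, entanglement, untangling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster import hierarchy

from oracles import naive_agglomerate, ols_normal_equations

from emsift.genome_scaling import (
    Dendrogram,
    build_dendrogram,
    entanglement,
    fit_count_vs_length,
    untangle,
)


class TestFitCountVsLength:
    def test_perfect_fit(self):
        lengths = [10.0, 20.0, 30.0, 40.0]
        counts = [2 * l for l in lengths]
        fit = fit_count_vs_length(counts, lengths)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_counts_r2_zero(self):
        fit = fit_count_vs_length([5.0] * 6, [10, 20, 30, 40, 50, 60])
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = [12.0, 35.0, 48.0, 60.0, 81.0]
        y = [100.0, 210.0, 260.0, 390.0, 420.0]
        fit = fit_count_vs_length(y, x)
        slope, intercept, r2, p = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_r2_invariant_to_affine_length_rescale(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(50, 150, size=18)
        y = 3 * x + rng.normal(0, 20, size=18)
        f1 = fit_count_vs_length(y, x)
        f2 = fit_count_vs_length(y, 7.3 * x + 11.0)
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_count_vs_length([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_count_vs_length([1, 2, 3], [5, 5, 5])

    def test_slope_recovery_on_simulated_scaling(self):
        """counts = c * length + noise: the 3-SE interval around the fitted
        slope covers c in (almost) all replicates, as the t-model predicts."""
        rng = np.random.default_rng(8)
        lengths = np.linspace(40, 160, 18)
        c = 12.0
        covered = 0
        n_reps = 100
        for _ in range(n_reps):
            counts = c * lengths + rng.normal(0, 15, size=18)
            fit = fit_count_vs_length(counts, lengths)
            resid = counts - (fit.intercept + fit.slope * lengths)
            se = np.sqrt(np.sum(resid**2) / 16
                         / np.sum((lengths - lengths.mean()) ** 2))
            covered += abs(fit.slope - c) < 3 * se
        # nominal coverage ~99.6% for +-3 SE with 16 df
        assert covered >= 95


class TestBuildDendrogram:
    def test_nearest_pair_merges_first(self):
        d = build_dendrogram({"a": 1.0, "b": 2.0, "c": 10.0})
        merged_first = {d.labels[int(i)] for i in d.linkage[0, :2]}
        assert merged_first == {"a", "b"}

    def test_tied_values_deterministic(self):
        d1 = build_dendrogram({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        d2 = build_dendrogram({"d": 1.0, "c": 1.0, "b": 1.0, "a": 1.0})
        assert d1.leaf_order == d2.leaf_order

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(21)
        values = {f"Chr{i:02d}": float(v)
                  for i, v in enumerate(rng.uniform(0, 100, size=6), start=1)}
        d = build_dendrogram(values)
        got = []
        tree = {i: frozenset([d.labels[i]]) for i in range(len(d.labels))}
        for row_i, row in enumerate(d.linkage):
            merged = tree[int(row[0])] | tree[int(row[1])]
            tree[len(d.labels) + row_i] = merged
            got.append((merged, float(row[2])))
        expected = naive_agglomerate(values)
        assert [m for m, _ in got] == [m for m, _ in expected]
        for (_, h1), (_, h2) in zip(got, expected):
            assert h1 == pytest.approx(h2, abs=1e-9)

    def test_heights_non_decreasing_and_order_is_permutation(self):
        rng = np.random.default_rng(33)
        values = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 12))}
        d = build_dendrogram(values)
        assert np.all(np.diff(d.heights) >= -1e-12)
        assert sorted(d.leaf_order) == sorted(values)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            build_dendrogram({"a": 1.0})


def _dendro_from_order(order):
    """A caterpillar dendrogram whose induced leaf order is exactly ``order``."""
    order = list(order)
    labels = sorted(order)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(order)
    rows = []
    prev = idx[order[0]]
    for h, label in enumerate(order[1:], start=1):
        rows.append([float(prev), float(idx[label]), float(h), float(h + 1)])
        prev = n + h - 1
    return Dendrogram(labels=labels, linkage=np.array(rows), leaf_order=order)


class TestEntanglement:
    def test_identical_orders_zero(self):
        d1 = _dendro_from_order("abcde")
        d2 = _dendro_from_order("abcde")
        assert entanglement(d1, d2).value == 0.0

    def test_reversed_orders_one(self):
        d1 = _dendro_from_order("abcde")
        d2 = _dendro_from_order("edcba")
        assert entanglement(d1, d2).value == pytest.approx(1.0)

    @given(seed=st.integers(0, 5000))
    def test_matches_direct_formula_on_random_permutation(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("abcde")
        perm = list(rng.permutation(labels))
        d1 = _dendro_from_order(labels)
        d2 = _dendro_from_order(perm)
        L = 1.5
        r1 = {l: i for i, l in enumerate(labels)}
        r2 = {l: i for i, l in enumerate(perm)}
        num = sum(abs(r1[l] - r2[l]) ** L for l in labels)
        den = sum(abs(i - (4 - i)) ** L for i in range(5))
        assert entanglement(d1, d2, L).value == pytest.approx(num / den)

    def test_symmetric_and_relabel_invariant(self):
        d1 = _dendro_from_order("abcde")
        d2 = _dendro_from_order("bacde")
        assert entanglement(d1, d2).value == entanglement(d2, d1).value
        e1 = entanglement(_dendro_from_order("pqrst"),
                          _dendro_from_order("qprst"))
        assert e1.value == entanglement(d1, d2).value

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            entanglement(_dendro_from_order("abc"), _dendro_from_order("abd"))


class TestUntangle:
    def test_aligned_trees_unchanged(self):
        d1 = _dendro_from_order("abcdef")
        d2 = _dendro_from_order("abcdef")
        o1, o2, score = untangle(d1, d2)
        assert o1.leaf_order == d1.leaf_order
        assert o2.leaf_order == d2.leaf_order
        assert score.value == 0.0 and score.untangled

    def test_single_swapped_subtree_resolves(self):
        # same merge structure; d2's deepest pair presented flipped
        d1 = _dendro_from_order("abcd")
        d2_raw = _dendro_from_order("abcd")
        d2 = Dendrogram(labels=d2_raw.labels, linkage=d2_raw.linkage,
                        leaf_order=["b", "a", "c", "d"])
        before = entanglement(d1, d2).value
        _, _, after = untangle(d1, d2)
        assert before > 0
        assert after.value < before

    @given(seed=st.integers(0, 5000))
    def test_never_increases_entanglement(self, seed):
        rng = np.random.default_rng(seed)
        v1 = {l: float(x) for l, x in zip("abcdefg", rng.uniform(0, 50, 7))}
        v2 = {l: float(x) for l, x in zip("abcdefg", rng.uniform(0, 50, 7))}
        d1, d2 = build_dendrogram(v1), build_dendrogram(v2)
        before = entanglement(d1, d2).value
        u1, u2, after = untangle(d1, d2)
        assert after.value <= before + 1e-12
        # idempotent at the fixed point reached
        _, _, again = untangle(u1, u2)
        assert again.value == pytest.approx(after.value, abs=1e-12)

    def test_comonotone_data_barely_entangled(self):
        """Length-clustered vs count-clustered trees can be aligned to near
        agreement when counts track length closely. (The raw scipy leaf
        order is convention-dependent under near-ties, so the invariant is
        asserted after untangling, which is how tanglegrams are read.)"""
        rng = np.random.default_rng(12)
        lengths = {f"Chr{i:02d}": float(l)
                   for i, l in enumerate(np.linspace(40, 160, 18), start=1)}
        counts = {c: 5.0 * v + float(rng.normal(0, 1.0)) for c, v in lengths.items()}
        d_len = build_dendrogram(lengths)
        d_cnt = build_dendrogram(counts)
        raw = entanglement(d_len, d_cnt).value
        _, _, aligned = untangle(d_len, d_cnt)
        assert aligned.value <= raw
        assert aligned.value < 0.1
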