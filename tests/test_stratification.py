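import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvstrat as pv
from pvstrat.stratification import (StratificationConfig, _entity_frequencies,
                                    choose_k, stratify_level)


def brute_force_kmeans(values, k):
    """Exhaustive search over contiguous partitions of the sorted values."""
    xs = sorted(values)
    n = len(xs)

    def sse(seg):
        m = sum(seg) / len(seg)
        return sum((x - m) ** 2 for x in seg)

    best = math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0,) + cuts + (n,)
        cost = sum(sse(xs[a:b]) for a, b in zip(edges, edges[1:]))
        best = min(best, cost)
    return best


def assignment_objective(values, asg):
    v = np.asarray(values, dtype=float)
    total = 0.0
    for lab in np.unique(asg.labels):
        seg = v[asg.labels == lab]
        total += ((seg - seg.mean()) ** 2).sum()
    return total


class TestLnFrequencies:
    def test_published_interval_endpoints(self):
        lnf = pv.ln_frequencies(pd.Series({"rare": 3, "top": 111_335}))
        assert round(lnf["rare"], 1) == 1.1
        assert round(lnf["top"], 1) == 11.6

    def test_frequency_one_maps_to_zero(self):
        assert pv.ln_frequencies(pd.Series({"x": 1}))["x"] == 0.0

    def test_rejects_zero_frequency(self):
        with pytest.raises(ValueError):
            pv.ln_frequencies(pd.Series({"x": 0}))


class TestHistogram:
    def test_hand_binning(self):
        assert list(pv.histogram([1.0, 1.2, 1.6], bin_width=0.5, origin=1.0)) == [2, 1]

    def test_single_value_single_bin(self):
        assert list(pv.histogram([3.7])) == [1]

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        assert pv.histogram(v).sum() == 500

    def test_max_value_lands_in_last_bin(self):
        # last bin is closed on the right
        counts = pv.histogram([0.0, 1.0], bin_width=0.5)
        assert counts.sum() == 2 and counts[-1] == 1


class TestCountPeaks:
    @pytest.mark.parametrize("bins,k", [
        ([1, 5, 1], 1),
        ([2, 7, 3, 1, 6, 2, 1, 4, 1], 3),   # three modes, like a real drug histogram
        ([3, 3, 3], 1),                      # flat: forced single cluster
        ([5, 1, 5], 2),                      # boundary runs count
        ([1, 4, 4, 1, 2], 2),                # plateau is one peak
    ])
    def test_peak_counting(self, bins, k):
        assert pv.count_peaks(bins) == k

    def test_clamped_to_max_k(self):
        bins = [1, 5, 1, 5, 1, 5, 1, 5, 1, 5, 1, 5, 1]
        assert pv.count_peaks(bins, max_k=5) == 5
        assert pv.count_peaks(bins, max_k=3) == 3


class TestKmeans1D:
    def test_k1_single_cluster_mean_center(self):
        asg = pv.kmeans_1d([1.0, 2.0, 6.0], 1)
        assert list(asg.labels) == [1, 1, 1]
        assert asg.centers[0] == pytest.approx(3.0)

    def test_separated_pairs(self):
        asg = pv.kmeans_1d([1.0, 1.1, 5.0, 5.1], 2)
        assert list(asg.labels) == [1, 1, 2, 2]
        assert asg.centers == pytest.approx([1.05, 5.05])

    def test_labels_ascend_with_value_order(self):
        asg = pv.kmeans_1d([5.0, 1.0, 5.1, 1.1], 2)
        assert list(asg.labels) == [2, 1, 2, 1]

    def test_ties_share_cluster(self):
        asg = pv.kmeans_1d([2.0, 2.0, 2.0, 9.0], 2)
        assert list(asg.labels) == [1, 1, 1, 2]

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            pv.kmeans_1d([1.0, 1.0, 2.0], 3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_optimality_vs_exhaustive_search(self, data):
        values = data.draw(st.lists(
            st.floats(min_value=-50, max_value=50,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=8))
        k = data.draw(st.integers(1, min(3, len(set(values)))))
        asg = pv.kmeans_1d(values, k)
        obj = assignment_objective(values, asg)
        best = brute_force_kmeans(values, k)
        assert obj == pytest.approx(best, abs=1e-7)

    def test_never_worse_than_lloyd(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(8)
        for _ in range(10):
            v = np.concatenate([rng.normal(0, 1, 20), rng.normal(6, 1, 20)])
            asg = pv.kmeans_1d(v, 3)
            km = sklearn.KMeans(n_clusters=3, n_init=5, random_state=0).fit(
                v.reshape(-1, 1))
            assert assignment_objective(v, asg) <= km.inertia_ + 1e-6


def bimodal_fixture():
    """2 drug modes x 2 ADR modes x 1 DEC mode -> exactly 4 leaves."""
    entries = {}
    for i in range(6):
        for j in range(3):
            entries[(f"L{i}", f"a{j}")] = 1
            entries[(f"L{i}", f"b{j}")] = 8
            entries[(f"H{i}", f"a{j}")] = 5
            entries[(f"H{i}", f"b{j}")] = 100
    return pv.DECCountTable.from_mapping(entries)


class TestStratifyLevel:
    def test_single_drug_forces_k1(self):
        counts = pv.DECCountTable.from_mapping({("D1", "A1"): 3, ("D1", "A2"): 5})
        labels, asg, _ = stratify_level(counts.counts, "drug", StratificationConfig())
        assert asg.k == 1 and set(labels) == {1}

    def test_two_frequency_modes_split(self):
        counts = pv.DECCountTable.from_mapping(
            {("D1", "A1"): 10, ("D2", "A1"): 20_000})
        cfg = StratificationConfig(min_entities=2)
        labels, asg, _ = stratify_level(counts.counts, "drug", cfg)
        assert asg.k == 2
        assert labels[("D1", "A1")] == 1 and labels[("D2", "A1")] == 2

    def test_min_entities_guard(self):
        counts = pv.DECCountTable.from_mapping(
            {("D1", "A1"): 10, ("D2", "A1"): 20_000})
        labels, asg, _ = stratify_level(counts.counts, "drug",
                                        StratificationConfig(min_entities=10))
        assert asg.k == 1

    def test_label_conservation(self, random_counts):
        labels, _, _ = stratify_level(random_counts.counts, "adr",
                                      StratificationConfig())
        assert len(labels) == len(random_counts)
        assert labels.notna().all()


class TestStratifyHierarchical:
    def test_unimodal_single_leaf(self):
        counts = pv.DECCountTable.from_mapping(
            {(f"D{i}", f"A{i % 3}"): 5 for i in range(12)})
        tree = pv.stratify_hierarchical(counts)
        assert list(tree.leaves) == ["1-1-1"]
        assert tree.total() == 60

    def test_engineered_two_by_two_modes(self):
        counts = bimodal_fixture()
        tree = pv.stratify_hierarchical(counts, StratificationConfig(min_entities=2))
        assert sorted(tree.leaves) == ["1-1-1", "1-2-1", "2-1-1", "2-2-1"]
        # low-frequency drugs' rare-ADR DECs all land in leaf 1-1-1
        leaf = tree.leaves["1-1-1"]
        assert set(leaf.index.get_level_values("drug")) == {f"L{i}" for i in range(6)}
        assert set(leaf.index.get_level_values("adr")) == {f"a{j}" for j in range(3)}

    def test_partition_and_dec_uniqueness(self, default_ds):
        counts = default_ds.counts()
        tree = pv.stratify_hierarchical(counts)
        assert tree.total() == counts.total()
        seen = [p for s in tree.leaves.values() for p in s.index]
        assert len(seen) == len(counts)
        assert len(set(seen)) == len(seen)
        assert tree.assignment.notna().all()

    def test_within_leaf_frequency_compression(self):
        counts = bimodal_fixture()
        tree = pv.stratify_hierarchical(counts, StratificationConfig(min_entities=2))
        global_ratio = counts.counts.max() / counts.counts.min()
        for leaf in tree.leaves.values():
            assert leaf.max() / leaf.min() <= global_ratio

    def test_metadata_export(self, tmp_path):
        counts = bimodal_fixture()
        tree = pv.stratify_hierarchical(counts, StratificationConfig(min_entities=2))
        out = tmp_path / "strata.csv"
        tree.write_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["level", "path", "entity_kind", "entity_id",
                                    "ln_frequency", "cluster_label"]
        assert set(df["level"]) == {1, 2, 3}
        drug_rows = df[df["entity_kind"] == "drug"]
        assert len(drug_rows) == 12


def test_choose_k_respects_distinct_values():
    lnf = pd.Series([0.0, 0.0, 5.0, 5.0])
    # two modes but only two distinct values; k stays feasible
    assert choose_k(lnf, StratificationConfig(min_entities=2)) <= 2


def test_entity_frequency_sums_conserved(random_counts):
    s = random_counts.counts
    for key in ("drug", "adr", "dec"):
        assert _entity_frequencies(s, key).sum() == random_counts.total()
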