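"""BIA, PCD and IDS: worked examples, oracle cross-checks, invariants."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from linkclust.clustering import (
    bia_cluster,
    build_dendrogram,
    cut_dendrogram,
    ids_cluster,
    pcd_cluster,
)
from linkclust.core_model import Clustering, InputError
from linkclust.distances import normalized_distance

from .conftest import make_record, make_spec, random_instance, threshold_graph_components


def three_chain_records():
    """Pairwise ed_all distances: (a,b)=1, (b,c)=1, (a,c)=2."""
    return [
        make_record("a", "dana", "lee", "19900101", "f", "06269"),
        make_record("b", "dane", "lee", "19900101", "f", "06269"),
        make_record("c", "dune", "lee", "19900101", "f", "06269"),
    ]


class TestDendrogram:
    def test_single_record(self):
        dend = build_dendrogram([make_record("a", "x", "y")], make_spec())
        assert dend.n_leaves == 1
        assert dend.root.is_leaf

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_dendrogram([], make_spec())

    def test_three_record_single_linkage_trace(self):
        # distances 1,1,2: first merge at level 1; single linkage pulls the
        # third record in at min(1,2)=1 as well
        recs = three_chain_records()
        spec = make_spec(mode="ed_all")
        dend = build_dendrogram(recs, spec)
        assert dend.root.level == 1.0
        assert not dend.root.is_leaf
        first_merge = dend.root.left if not dend.root.left.is_leaf else dend.root.right
        assert first_merge.level == 1.0

    def test_identical_records_merge_at_zero(self):
        recs = [make_record(f"r{i}", "ann", "lee", "19900101", "f", "11111")
                for i in range(5)]
        dend = build_dendrogram(recs, make_spec())
        assert dend.root.level == 0.0

    def test_merge_levels_non_decreasing_to_root(self):
        records, _ = random_instance(9, 20)
        dend = build_dendrogram(records, make_spec(mode="ed_all", value=3))
        stack = [dend.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                assert node.left.level <= node.level
                assert node.right.level <= node.level
                stack.extend([node.left, node.right])

    def test_levels_match_scipy_single_linkage(self):
        """Merge-level multiset agrees with scipy's single-linkage oracle."""
        records, _ = random_instance(13, 25)
        records = records[:40]
        spec = make_spec(mode="ed_all")
        n = len(records)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = normalized_distance(records[i], records[j], spec)
        z = sch.linkage(squareform(mat), method="single")
        dend = build_dendrogram(records, spec)
        ours = []
        stack = [dend.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                ours.append(node.level)
                stack.extend([node.left, node.right])
        assert sorted(ours) == pytest.approx(sorted(z[:, 2]))

    def test_newick_dump_parses_leaf_count(self):
        dend = build_dendrogram(three_chain_records(), make_spec())
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for rid in ("a", "b", "c"):
            assert rid in nwk


class TestCut:
    def test_cut_extremes(self):
        recs = three_chain_records()
        dend = build_dendrogram(recs, make_spec(mode="ed_all"))
        assert len(cut_dendrogram(dend, 0.5)) == 3  # below all merges
        assert len(cut_dendrogram(dend, 10)) == 1  # above the root

    def test_cut_traced_example(self):
        dend = build_dendrogram(three_chain_records(), make_spec(mode="ed_all"))
        at1 = cut_dendrogram(dend, 1)
        assert at1 == Clustering.from_groups([{"a", "b", "c"}])

    def test_scipy_fcluster_same_partition(self):
        records, _ = random_instance(21, 20)
        spec = make_spec(mode="ed_all")
        n = len(records)
        ids = [r.record_id for r in records]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = normalized_distance(records[i], records[j], spec)
        z = sch.linkage(squareform(mat), method="single")
        for t in (0, 1, 2, 4):
            labels = sch.fcluster(z, t=t, criterion="distance")
            oracle = {}
            for rid, lab in zip(ids, labels):
                oracle.setdefault(lab, set()).add(rid)
            assert cut_dendrogram(build_dendrogram(records, spec), t) == Clustering(
                {str(k): v for k, v in oracle.items()}
            )


class TestIDS:
    def test_empty_input_empty_clustering(self):
        assert len(ids_cluster([], make_spec(), 1)) == 0

    def test_transitive_chain(self):
        # a-b and b-c within threshold 1, a-c at distance 2: one cluster
        clustering = ids_cluster(three_chain_records(), make_spec(mode="ed_all"), 1)
        assert clustering == Clustering.from_groups([{"a", "b", "c"}])

    def test_no_passing_pairs_all_singletons(self):
        records, _ = random_instance(17, 15, duplicates_max=1)
        clustering = ids_cluster(records, make_spec(mode="ed_all"), 0)
        assert len(clustering) == len(records)

    def test_matches_graph_components_oracle(self):
        for seed in range(6):
            records, _ = random_instance(seed, 12)
            for mode, kind, value in (
                ("ed_all", "constant", 2),
                ("rded", "constant", 3),
                ("pded", "proportional", 0.1),
            ):
                spec = make_spec(mode=mode, kind=kind, value=value)
                got = ids_cluster(records, spec, value).as_sets()
                assert got == threshold_graph_components(records, spec, value)


class TestEquivalenceAndMonotonicity:
    @pytest.mark.parametrize("mode,kind,value", [
        ("ed_all", "constant", 2),
        ("nded", "constant", 3),
        ("pded", "proportional", 0.15),
    ])
    def test_three_way_equivalence(self, mode, kind, value):
        for seed in range(5):
            records, _ = random_instance(100 + seed, 15)
            spec = make_spec(mode=mode, kind=kind, value=value)
            a = bia_cluster(records, spec, value)
            b = pcd_cluster(records, spec, value)
            c = ids_cluster(records, spec, value)
            assert a == b == c

    def test_threshold_monotonicity(self):
        records, _ = random_instance(31, 20)
        spec = make_spec(mode="ed_all")
        prev = None
        for t in (0, 1, 2, 3, 5, 8):
            cur = ids_cluster(records, spec, t)
            if prev is not None:
                assert prev.refines(cur)
                assert len(cur) <= len(prev)
            prev = cur

    def test_order_invariance(self):
        records, _ = random_instance(41, 15)
        spec = make_spec(mode="ed_all", value=2)
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        for algo in (bia_cluster, pcd_cluster, ids_cluster):
            assert algo(records, spec, 2) == algo(shuffled, spec, 2)
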