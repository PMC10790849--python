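"""Region-level edge patterns, Jaccard distances, UPGMA clustering, and
per-cluster common edges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jaccard as scipy_jaccard

from drivefc import (
    AAL116,
    EdgePattern,
    cluster_common_edges,
    edges_to_region_matrix,
    jaccard_distance,
    pair_to_edge,
    upgma_cluster,
)
from drivefc.interpretation import common_network_pairs, pairwise_jaccard


def _pattern(edges, participant="p"):
    """Build an EdgePattern from (region_index, region_index) pairs."""
    m = np.zeros((116, 116), dtype=np.uint8)
    for i, j in edges:
        m[i, j] = m[j, i] = 1
    return EdgePattern(participant=participant, matrix=m)


def _region_index(name):
    return AAL116.index(name)


class TestEdgesToRegionMatrix:
    def test_empty_edge_set_zero_matrix(self, montage):
        pat = edges_to_region_matrix([], montage)
        assert pat.matrix.sum() == 0

    def test_single_edge_sets_one_region_pair(self, montage):
        # channels 0 and 24 lie in Frontal_Sup_L and Precentral_L
        e = pair_to_edge(0, 24)
        pat = edges_to_region_matrix([e], montage)
        a = _region_index("Frontal_Sup_L")
        b = _region_index("Precentral_L")
        assert pat.matrix[a, b] == 1 and pat.matrix[b, a] == 1
        assert pat.matrix.sum() == 2

    def test_within_region_pair_sets_diagonal(self, montage):
        e = pair_to_edge(0, 1)  # both channels in Frontal_Sup_L
        pat = edges_to_region_matrix([e], montage)
        a = _region_index("Frontal_Sup_L")
        assert pat.matrix[a, a] == 1

    def test_channel_pairs_collapsing_to_region_pairs(self, montage):
        # channels 0,1 -> Frontal_Sup_L; 24,25 -> Precentral_L;
        # 8 -> Frontal_Mid_L: three channel pairs, two region pairs
        edges = [pair_to_edge(0, 24), pair_to_edge(1, 25), pair_to_edge(0, 8)]
        pat = edges_to_region_matrix(edges, montage)
        assert len(pat.edge_set()) == 2

    def test_unknown_region_rejected(self, montage):
        bad = montage.copy()
        bad.loc[0, "aal_region"] = "Not_A_Region"
        with pytest.raises(ValueError, match="unknown region"):
            edges_to_region_matrix([0], bad)


class TestJaccard:
    def test_identical_patterns_distance_zero(self):
        p = _pattern([(0, 1), (2, 3)])
        assert jaccard_distance(p, p) == 0.0

    def test_disjoint_patterns_distance_one(self):
        a = _pattern([(0, 1)])
        b = _pattern([(2, 3), (4, 5)])
        assert jaccard_distance(a, b) == 1.0

    def test_set_arithmetic_example(self):
        # |A & B| = 2, |A | B| = 5 -> distance 0.6
        a = _pattern([(0, 1), (2, 3), (4, 5), (6, 7)])
        b = _pattern([(0, 1), (2, 3), (8, 9)])
        assert jaccard_distance(a, b) == pytest.approx(0.6)

    def test_both_empty_warns_and_returns_zero(self):
        a, b = _pattern([]), _pattern([], "q")
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard_distance(a, b) == 0.0

    def test_matches_scipy_on_flattened_vectors(self, rng):
        for _ in range(5):
            ea = [tuple(sorted(rng.integers(0, 20, 2))) for _ in range(6)]
            eb = [tuple(sorted(rng.integers(0, 20, 2))) for _ in range(6)]
            a, b = _pattern(ea), _pattern(eb)
            iu = np.triu_indices(116)
            va = a.matrix[iu].astype(bool)
            vb = b.matrix[iu].astype(bool)
            assert jaccard_distance(a, b) == pytest.approx(
                scipy_jaccard(va, vb)
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        pats = []
        for k in range(3):
            edges = [
                tuple(sorted(rng.integers(0, 12, 2))) for _ in range(4)
            ]
            pats.append(_pattern(edges, str(k)))
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            d01 = jaccard_distance(pats[0], pats[1])
            d12 = jaccard_distance(pats[1], pats[2])
            d02 = jaccard_distance(pats[0], pats[2])
        assert d02 <= d01 + d12 + 1e-12


def naive_upgma(dist):
    """Textbook UPGMA: repeatedly merge the closest clusters, averaging
    distances weighted by cluster size.  Returns merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    heights = []
    nxt = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(a) + clusters.pop(b)
        newd = {}
        for key in list(d):
            if a in key or b in key:
                del d[key]
        for c, members in clusters.items():
            acc = sum(dist[x, y] for x in merged for y in members)
            newd[(min(c, nxt), max(c, nxt))] = acc / (
                len(merged) * len(members)
            )
        clusters[nxt] = merged
        # rebuild pairwise distances among remaining clusters
        for key, v in newd.items():
            d[key] = v
        nxt += 1
    return np.array(heights)


class TestUPGMA:
    def test_identical_patterns_merge_at_zero(self):
        p1 = _pattern([(0, 1)], "a")
        p2 = _pattern([(0, 1)], "b")
        p3 = _pattern([(5, 6)], "c")
        tree = upgma_cluster([p1, p2, p3], n_clusters=2)
        assert tree.linkage[0, 2] == 0.0
        assert tree.assignments[0] == tree.assignments[1]

    def test_block_structure_two_tight_pairs(self):
        pats = [
            _pattern([(0, 1), (0, 2)], "a"),
            _pattern([(0, 1), (0, 3)], "b"),
            _pattern([(10, 11), (10, 12)], "c"),
            _pattern([(10, 11), (10, 13)], "d"),
        ]
        tree = upgma_cluster(pats, n_clusters=2)
        a = tree.assignments
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]

    def test_merge_heights_match_naive_oracle(self, rng):
        pats = []
        for k in range(5):
            edges = [
                tuple(sorted(rng.integers(0, 30, 2))) for _ in range(5)
            ]
            pats.append(_pattern(edges, str(k)))
        from scipy.spatial.distance import squareform

        dist = squareform(pairwise_jaccard(pats))
        expect = np.sort(naive_upgma(dist))
        tree = upgma_cluster(pats, n_clusters=2)
        assert np.allclose(np.sort(tree.linkage[:, 2]), expect, atol=1e-12)

    def test_merge_heights_nondecreasing(self, rng):
        pats = [
            _pattern(
                [tuple(sorted(rng.integers(0, 25, 2))) for _ in range(4)],
                str(k),
            )
            for k in range(8)
        ]
        tree = upgma_cluster(pats, n_clusters=3)
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)

    def test_input_order_invariance_up_to_relabeling(self, rng):
        pats = [
            _pattern(
                [tuple(sorted(rng.integers(0, 40, 2))) for _ in range(5)],
                str(k),
            )
            for k in range(6)
        ]
        t1 = upgma_cluster(pats, n_clusters=3)
        order = [3, 0, 5, 1, 4, 2]
        t2 = upgma_cluster([pats[i] for i in order], n_clusters=3)
        part1 = {
            frozenset(t1.participants[i] for i in t1.members(c))
            for c in t1.cluster_ids
        }
        part2 = {
            frozenset(t2.participants[i] for i in t2.members(c))
            for c in t2.cluster_ids
        }
        assert part1 == part2

    def test_too_many_clusters_rejected(self):
        pats = [_pattern([(0, 1)], "a"), _pattern([(2, 3)], "b")]
        with pytest.raises(ValueError):
            upgma_cluster(pats, n_clusters=3)

    def test_single_pattern_rejected(self):
        with pytest.raises(ValueError):
            upgma_cluster([_pattern([(0, 1)])], n_clusters=1)


class TestCommonEdges:
    def test_singleton_cluster_keeps_own_pattern(self):
        p1 = _pattern([(0, 1), (2, 3)], "a")
        p2 = _pattern([(50, 60)], "b")
        tree = upgma_cluster([p1, p2], n_clusters=2)
        common = cluster_common_edges(tree)
        sizes = sorted(len(v) for v in common.values())
        assert sizes == [1, 2]

    def test_disjoint_members_empty_common_set(self):
        p1 = _pattern([(0, 1)], "a")
        p2 = _pattern([(2, 3)], "b")
        tree = upgma_cluster([p1, p2], n_clusters=1)
        common = cluster_common_edges(tree)
        assert list(common.values()) == [[]]

    def test_network_annotation_of_planted_pairs(self):
        dan = _region_index("Frontal_Sup_L")
        smn = _region_index("Precentral_L")
        van = _region_index("Frontal_Mid_L")
        shared = [(dan, smn), (dan, van)]
        pats = [
            _pattern(shared + [(80 + k, 81 + k)], str(k)) for k in range(4)
        ]
        tree = upgma_cluster(pats, n_clusters=2)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            nets = common_network_pairs(cluster_common_edges(tree))
        for pairs in nets.values():
            assert ("DAN", "SMN") in pairs
            assert ("DAN", "VAN") in pairs

    def test_common_sets_shrink_as_clusters_merge(self, rng):
        pats = [
            _pattern(
                [(0, 1)]
                + [tuple(sorted(rng.integers(2, 30, 2))) for _ in range(4)],
                str(k),
            )
            for k in range(6)
        ]
        sizes = []
        for k in (6, 3, 1):
            tree = upgma_cluster(pats, n_clusters=k)
            common = cluster_common_edges(tree)
            sizes.append(max(len(v) for v in common.values()))
        assert sizes[0] >= sizes[1] >= sizes[2] >= 1  # (0,1) always shared

    def test_unlabeled_region_warns_unassigned(self):
        p1 = _pattern([(100, 101)], "a")
        p2 = _pattern([(100, 101)], "b")
        tree = upgma_cluster([p1, p2], n_clusters=1)
        with pytest.warns(UserWarning, match="no network label"):
            common = cluster_common_edges(tree)
        (recs,) = common.values()
        assert recs[0]["networks"] == ("unassigned", "unassigned")
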