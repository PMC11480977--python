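import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from glycodock.clustering import (RMSDMatrix, cluster_hier, cluster_report,
                                  rank_clusters, rmsd_matrix,
                                  select_top_clusters)
from glycodock.evaluation import kabsch_superpose
from glycodock.fixtures import make_decoys


def brute_force_average_linkage(square: np.ndarray, cut_kind: str,
                                cut_value: float) -> list[frozenset]:
    """Naive agglomerative average-linkage: repeatedly merge the pair of
    clusters with minimal mean inter-cluster distance."""
    n = square.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([square[i, j] for i in clusters[a]
                         for j in clusters[b]])
            if d < best:
                best, pair = d, (a, b)
        if cut_kind == "distance" and best > cut_value:
            break
        if cut_kind == "n_clusters" and len(clusters) <= cut_value:
            break
        a, b = pair
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return clusters


@pytest.fixture(scope="module")
def decoys(toy3):
    rng = np.random.default_rng(0)
    requests = [0.0, 0.3, 0.5, 4.0, 4.3, 4.5, 9.0, 9.5]
    return make_decoys(toy3, requests, seed=1)


class TestRmsdMatrix:
    def test_duplicate_models_zero(self, toy3, decoys):
        pair = [decoys.models[0], decoys.models[0]]
        m = rmsd_matrix(pair, toy3.receptor, toy3.reference, mode="ti-aa")
        assert m.condensed[0] == pytest.approx(0.0, abs=1e-9)

    def test_translated_copy_zero_after_superposition(self, toy3, decoys):
        m0 = decoys.models[0]
        from dataclasses import replace
        shifted = replace(m0, ligand=m0.ligand.with_coords(
            m0.ligand.coords() + 1.0),
            receptor=toy3.receptor.with_coords(toy3.receptor.coords() + 1.0))
        m = rmsd_matrix([m0, shifted], toy3.receptor, toy3.reference,
                        mode="tip-ap")
        assert m.condensed[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_pair_kabsch_oracle(self, toy3, decoys):
        models = decoys.models[:5]
        mat = rmsd_matrix(models, toy3.receptor, toy3.reference, mode="tip-ap")
        sq = mat.square()
        from glycodock.structures import select_interface
        iface, _ = select_interface(*toy3.reference, cutoff=3.9)
        keys = [r.key for r in iface]
        def sel(m):
            rmap = {r.key: r for r in toy3.receptor.residues}
            parts = [rmap[k].heavy_coords() for k in keys]
            parts += [r.heavy_coords() for r in m.ligand.residues]
            return np.vstack(parts)
        for i in range(5):
            for j in range(i + 1, 5):
                _, _, r = kabsch_superpose(sel(models[i]), sel(models[j]))
                assert sq[i, j] == pytest.approx(r, abs=1e-9)

    def test_text_round_trip(self, toy3, decoys, tmp_path):
        mat = rmsd_matrix(decoys.models[:4], toy3.receptor, toy3.reference)
        p = tmp_path / "matrix.txt"
        mat.to_text(p)
        back = RMSDMatrix.from_text(p)
        assert back.model_ids == mat.model_ids
        np.testing.assert_allclose(back.condensed, mat.condensed, atol=1e-6)

    def test_atom_mismatch_rejected(self, toy3, decoys):
        bad = decoys.models[1]
        bad = type(bad)(**{**bad.__dict__})
        bad.ligand = bad.ligand.copy()
        bad.ligand.residues = bad.ligand.residues[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_matrix([decoys.models[0], bad], toy3.receptor,
                        toy3.reference, mode="tip-ap")


def _matrix_from_square(sq):
    n = sq.shape[0]
    return RMSDMatrix(n, squareform(sq, checks=False), list(range(n)), "ti-aa")


class TestClusterHier:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 0.3, 6), rng.normal(10, 0.3, 6)])
        sq = np.abs(pts[:, None] - pts[None, :])
        cs = cluster_hier(_matrix_from_square(sq),
                          {i: float(i) for i in range(12)},
                          cut=("distance", 2.5), min_size=4)
        assert len(cs) == 2
        assert sorted(len(c.members) for c in cs.clusters) == [6, 6]

    def test_all_close_single_cluster(self):
        rng = np.random.default_rng(2)
        sq = rng.uniform(0.1, 1.0, size=(8, 8))
        sq = (sq + sq.T) / 2
        np.fill_diagonal(sq, 0)
        cs = cluster_hier(_matrix_from_square(sq),
                          {i: 0.0 for i in range(8)}, cut=("distance", 2.5))
        assert len(cs) == 1 and len(cs.clusters[0].members) == 8

    def test_min_size_filtering_keeps_pool(self):
        pts = np.array([0.0, 0.1, 0.2, 0.3, 50.0])
        sq = np.abs(pts[:, None] - pts[None, :])
        cs = cluster_hier(_matrix_from_square(sq),
                          {i: float(i) for i in range(5)},
                          cut=("distance", 2.5), min_size=4)
        assert len(cs) == 1
        assert cs.unclustered == [4]

    def test_too_many_clusters_requested(self):
        sq = np.ones((3, 3)); np.fill_diagonal(sq, 0)
        with pytest.raises(ValueError):
            cluster_hier(_matrix_from_square(sq), {i: 0.0 for i in range(3)},
                         cut=("n_clusters", 5))

    @pytest.mark.parametrize("cut", [("distance", 0.5), ("distance", 1.5),
                                     ("n_clusters", 2), ("n_clusters", 4)])
    def test_matches_brute_force_enumeration(self, cut):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            sq = rng.uniform(0.05, 3.0, size=(n, n))
            sq = (sq + sq.T) / 2
            np.fill_diagonal(sq, 0)
            if cut[0] == "n_clusters" and cut[1] > n:
                continue
            cs = cluster_hier(_matrix_from_square(sq),
                              {i: float(i) for i in range(n)},
                              cut=cut, min_size=1)
            mine = {frozenset(c.members) for c in cs.clusters}
            oracle = set(brute_force_average_linkage(sq, *cut))
            assert mine == oracle, f"trial {trial} n={n}"

    def test_order_invariance(self, toy3, decoys):
        models = decoys.models
        scores = {m.model_id: m.score for m in models}
        mat1 = rmsd_matrix(models, toy3.receptor, toy3.reference, mode="tip-ap")
        perm = [models[i] for i in (3, 0, 5, 1, 7, 2, 6, 4)]
        mat2 = rmsd_matrix(perm, toy3.receptor, toy3.reference, mode="tip-ap")
        c1 = cluster_hier(mat1, scores, cut=("distance", 2.5), min_size=1)
        c2 = cluster_hier(mat2, scores, cut=("distance", 2.5), min_size=1)
        assert {frozenset(c.members) for c in c1.clusters} == \
            {frozenset(c.members) for c in c2.clusters}

    def test_nesting_as_distance_grows(self):
        rng = np.random.default_rng(9)
        sq = rng.uniform(0.1, 4.0, size=(8, 8))
        sq = (sq + sq.T) / 2
        np.fill_diagonal(sq, 0)
        prev = None
        for d in (0.5, 1.0, 2.0, 4.5):
            cs = cluster_hier(_matrix_from_square(sq),
                              {i: 0.0 for i in range(8)},
                              cut=("distance", d), min_size=1)
            parts = {frozenset(c.members) for c in cs.clusters}
            if prev is not None:
                # every earlier cluster is contained in some later cluster
                for small in prev:
                    assert any(small <= big for big in parts)
            prev = parts


class TestRanking:
    def _set(self, member_scores):
        from glycodock.clustering import Cluster, ClusterSet
        clusters = []
        scores = {}
        mid = 0
        for cid, ms in enumerate(member_scores):
            members = []
            for s in ms:
                scores[mid] = s
                members.append(mid)
                mid += 1
            members.sort(key=lambda m: (scores[m], m))
            clusters.append(Cluster(cid, members))
        return ClusterSet(clusters, [], 1, ("distance", 2.5)), scores

    def test_mean_of_top4(self):
        cs, scores = self._set([[-10, -8, -6, -4, -2]])
        ranked = rank_clusters(cs, scores, top_k=4)
        assert ranked.clusters[0].rank_score == pytest.approx(-7.0)

    def test_tie_break_by_cluster_id(self):
        cs, scores = self._set([[-5.0], [-5.0]])
        ranked = rank_clusters(cs, scores, top_k=4)
        assert [c.cluster_id for c in ranked.clusters] == [0, 1]

    def test_selection_sizes(self):
        cs, scores = self._set([[1] * 6, [2] * 5, [3] * 4])
        ranked = rank_clusters(cs, scores)
        sel = select_top_clusters(ranked, models_per_cluster=5)
        assert len(sel) == 5 + 5 + 4

    def test_empty_selection_warns(self):
        from glycodock.clustering import ClusterSet
        empty = ClusterSet([], [], 4, ("distance", 2.5))
        with pytest.warns(UserWarning):
            assert select_top_clusters(empty) == []

    def test_report_frame(self):
        cs, scores = self._set([[1, 2, 3, 4]])
        ranked = rank_clusters(cs, scores)
        frame = cluster_report(ranked)
        assert list(frame.columns) == ["cluster_id", "size", "rank_score",
                                       "member_ids"]
        assert frame.iloc[0]["size"] == 4
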