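"""Pairwise RMSD matrices over docking models and hierarchical clustering.

Models are compared on a selection matched to the restraint scenario: all
interface residues (ti-aa) or the protein interface residues plus the whole
glycan (tip-ap), heavy atoms only, with pairwise Kabsch superposition on the
same selection.  Clustering is agglomerative with average linkage, cut
either at a distance threshold (2.5 A default) or into a requested number
of flat clusters; clusters below the minimum size (4) are dropped from
reporting but their members are retained in an unclustered pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .evaluation import kabsch_superpose
from .rigid_docking import DockingModel
from .structures import Structure, select_interface

__all__ = ["RMSDMatrix", "Cluster", "ClusterSet", "rmsd_matrix",
           "cluster_hier", "rank_clusters", "select_top_clusters",
           "cluster_report"]


@dataclass
class RMSDMatrix:
    n_models: int
    condensed: np.ndarray       # length n(n-1)/2, A
    model_ids: list[int]
    selection_mode: str         # ti-aa | tip-ap

    def __post_init__(self) -> None:
        if len(self.condensed) != self.n_models * (self.n_models - 1) // 2:
            raise ValueError("condensed length inconsistent with n_models")
        if (self.condensed < 0).any():
            raise ValueError("negative distances")

    def square(self) -> np.ndarray:
        return squareform(self.condensed)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# model_ids\t" + "\t".join(map(str, self.model_ids)) + "\n")
            fh.write(f"# selection_mode\t{self.selection_mode}\n")
            for v in self.condensed:
                fh.write(f"{v:.6f}\n")

    @classmethod
    def from_text(cls, path) -> "RMSDMatrix":
        ids, mode, vals = [], "", []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# model_ids"):
                    ids = [int(x) for x in line.split("\t")[1:]]
                elif line.startswith("# selection_mode"):
                    mode = line.split("\t")[1].strip()
                elif line.strip():
                    vals.append(float(line))
        return cls(len(ids), np.array(vals), ids, mode)


def _selection_coords(model: DockingModel, receptor: Structure,
                      rec_res_keys: list[tuple],
                      lig_res_keys: list[tuple]) -> np.ndarray:
    rec = model.receptor if model.receptor is not None else receptor
    parts = []
    rmap = {r.key: r for r in rec.residues}
    lmap = {r.key: r for r in model.ligand.residues}
    try:
        for k in rec_res_keys:
            parts.append(rmap[k].heavy_coords())
        for k in lig_res_keys:
            parts.append(lmap[k].heavy_coords())
    except KeyError as exc:
        raise ValueError(f"atom-count mismatch between models: model "
                         f"{model.model_id} lacks residue {exc}") from exc
    return np.vstack(parts)


def rmsd_matrix(models: list[DockingModel], receptor: Structure,
                reference: tuple[Structure, Structure],
                mode: str = "ti-aa", interface_cutoff: float = 3.9,
                superpose: str = "pairwise") -> RMSDMatrix:
    """Pairwise heavy-atom RMSD matrix over the scenario's selection.

    ``reference`` (a bound receptor/ligand pair) defines the interface
    residues.  ``superpose='pairwise'`` fits each model pair on the selection
    before measuring; ``'none'`` assumes a shared receptor frame.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    ref_r, ref_l = reference
    iface_r, iface_l = select_interface(ref_r, ref_l, cutoff=interface_cutoff)
    rec_keys = [r.key for r in iface_r]
    if mode == "ti-aa":
        lig_keys = [r.key for r in iface_l]
    elif mode == "tip-ap":
        lig_keys = [r.key for r in models[0].ligand.residues]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    sels = [_selection_coords(m, receptor, rec_keys, lig_keys) for m in models]
    n_atoms = {s.shape[0] for s in sels}
    if len(n_atoms) != 1:
        raise ValueError("atom-count mismatch between models")
    n = len(models)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if superpose == "pairwise":
                _, _, r = kabsch_superpose(sels[i], sels[j])
            else:
                r = float(np.sqrt(np.mean(np.sum((sels[i] - sels[j]) ** 2, axis=1))))
            out[k] = r
            k += 1
    return RMSDMatrix(n, out, [m.model_id for m in models], mode)


@dataclass
class Cluster:
    cluster_id: int
    members: list[int]          # model ids, sorted by (score, model_id)
    rank_score: float | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    unclustered: list[int]
    min_size: int
    cut: tuple[str, float]      # ("distance", 2.5) or ("n_clusters", 50)

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_hier(matrix: RMSDMatrix, scores: dict[int, float],
                 cut: tuple[str, float] = ("distance", 2.5),
                 min_size: int = 4) -> ClusterSet:
    """Average-linkage agglomerative clustering of an RMSD matrix.

    The dendrogram is cut at a distance threshold or into exactly N flat
    clusters (before size filtering, so fewer than N may be reported).
    Members are sorted by (score, model_id); clusters by cluster id.
    """
    kind, value = cut
    if kind == "n_clusters" and value > matrix.n_models:
        raise ValueError("requested more clusters than models")
    z = linkage(matrix.condensed, method="average")
    if kind == "distance":
        flat = fcluster(z, t=value, criterion="distance")
    elif kind == "n_clusters":
        flat = fcluster(z, t=int(value), criterion="maxclust")
    else:
        raise ValueError(f"unknown cut kind {kind!r}")
    groups: dict[int, list[int]] = {}
    for mid, g in zip(matrix.model_ids, flat):
        groups.setdefault(int(g), []).append(mid)
    clusters, pool = [], []
    cid = 0
    for g in sorted(groups):
        members = sorted(groups[g], key=lambda m: (scores[m], m))
        if len(members) >= min_size:
            clusters.append(Cluster(cid, members))
            cid += 1
        else:
            pool.extend(members)
    return ClusterSet(clusters, sorted(pool), min_size, cut)


def rank_clusters(cluster_set: ClusterSet, scores: dict[int, float],
                  top_k: int = 4) -> ClusterSet:
    """Rank clusters by the mean score of their best ``top_k`` members
    (fewer if smaller); ties broken by lower cluster id."""
    for c in cluster_set.clusters:
        best = sorted(scores[m] for m in c.members)[:top_k]
        c.rank_score = float(np.mean(best))
    cluster_set.clusters.sort(key=lambda c: (c.rank_score, c.cluster_id))
    return cluster_set


def select_top_clusters(cluster_set: ClusterSet,
                        models_per_cluster: int = 5) -> list[int]:
    """Model ids of each ranked cluster's best members, concatenated in
    cluster-rank order; feeds the flexible-refinement stage."""
    import warnings

    if not cluster_set.clusters:
        warnings.warn("empty cluster set: nothing selected", stacklevel=2)
        return []
    out = []
    for c in cluster_set.clusters:
        out.extend(c.members[:models_per_cluster])
    return out


def cluster_report(cluster_set: ClusterSet) -> pd.DataFrame:
    rows = [{"cluster_id": c.cluster_id, "size": len(c.members),
             "rank_score": c.rank_score,
             "member_ids": ";".join(map(str, c.members))}
            for c in cluster_set.clusters]
    return pd.DataFrame(rows)
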