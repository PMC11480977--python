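"""Glycan conformer presampling for ensemble docking.

Members are generated by perturbing the glycosidic dihedrals (phi about the
anomeric C-O bond, psi about the O-C bond of the accepting unit) with
Gaussian deviates whose width scales with the square root of an "effort"
multiplier, followed by a clash-relaxing restrained minimization; rings are
kept rigid by the same stiff bond / 1-3 distance restraints used in
refinement.  The ensemble can then be reduced to representative cluster
centers by hierarchical RMSD clustering, which are used as the starting
conformations for ensemble docking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .evaluation import CorrespondenceError, kabsch_superpose
from .refinement import _one_three, _pair_energy_grad, build_bond_graph
from .structures import GlycanTopology, Structure

__all__ = ["ConformerEnsemble", "sample_conformers", "reduce_to_centers",
           "rmsd_to_reference"]

CLASH_DISTANCE = 2.2  # A, heavy-atom clash criterion within the glycan
SIGMA_BASE_DEG = 20.0


@dataclass
class ConformerEnsemble:
    members: list[Structure]
    provenance: dict = field(default_factory=dict)
    rmsd_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = {len(m.atoms) for m in self.members}
        if len(counts) > 1:
            raise ValueError("ensemble members differ in atom count")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class _Linkage:
    donor_res: int        # residue index providing the anomeric carbon
    acceptor_res: int
    c_idx: int            # heavy-atom indices into the glycan heavy array
    o_idx: int
    c2_idx: int           # the accepting carbon bonded to the oxygen
    moving: np.ndarray    # heavy-atom indices rotated by this linkage


def _analyze_linkages(glycan: Structure, topology: GlycanTopology
                      ) -> list[_Linkage]:
    import networkx as nx

    xyz = glycan.heavy_coords()
    res_of = glycan.heavy_residue_index()
    elements = np.array([a.element.upper() for r in glycan.residues
                         for a in r.heavy_atoms])
    g = nx.Graph()
    g.add_nodes_from(range(len(glycan.residues)))
    g.add_edges_from(topology.linkage_edges)
    out = []
    for (i, j) in sorted(topology.linkage_edges):
        # identify the bridging C (anomeric) / O pair across the edge
        ii = np.where(res_of == i)[0]
        jj = np.where(res_of == j)[0]
        d = cdist(xyz[ii], xyz[jj])
        best, c_idx, o_idx, donor = np.inf, -1, -1, i
        for a in range(len(ii)):
            for b in range(len(jj)):
                if d[a, b] > 1.8:
                    continue
                ea, eb = elements[ii[a]], elements[jj[b]]
                if {ea, eb} == {"C", "O"} and d[a, b] < best:
                    best = d[a, b]
                    if ea == "C":
                        c_idx, o_idx, donor = ii[a], jj[b], i
                    else:
                        c_idx, o_idx, donor = jj[b], ii[a], j
        if c_idx < 0:
            raise ValueError(f"no glycosidic C-O bond found for edge {(i, j)}")
        acceptor = j if donor == i else i
        # the accepting carbon: nearest same-residue carbon to the oxygen
        acc_atoms = np.where(res_of == acceptor)[0]
        cands = acc_atoms[(elements[acc_atoms] == "C")]
        c2_idx = int(cands[np.argmin(np.linalg.norm(xyz[cands] - xyz[o_idx],
                                                    axis=1))])
        # residues moved by this linkage: component holding the acceptor
        # when the edge is removed, taking residue 0 as the fixed root
        h = g.copy()
        h.remove_edge(i, j)
        comp_d = nx.node_connected_component(h, donor)
        comp_a = nx.node_connected_component(h, acceptor)
        moving_res = comp_a if 0 in comp_d else comp_d
        moving = np.concatenate([np.where(res_of == r)[0]
                                 for r in sorted(moving_res)])
        out.append(_Linkage(donor, acceptor, int(c_idx), int(o_idx), c2_idx,
                            moving))
    return out


def _rotate_subtree(xyz: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                    moving: np.ndarray, angle: float) -> None:
    if angle == 0.0:
        return
    axis = p1 - p0
    n = np.linalg.norm(axis)
    if n < 1e-9:
        return
    rot = Rotation.from_rotvec(axis / n * angle)
    xyz[moving] = rot.apply(xyz[moving] - p0) + p0


def _has_clash(xyz: np.ndarray, res_of: np.ndarray,
               adjacency: set[tuple[int, int]]) -> bool:
    d = cdist(xyz, xyz)
    n = len(xyz)
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = int(res_of[a]), int(res_of[b])
            if ra == rb or (min(ra, rb), max(ra, rb)) in adjacency:
                continue
            if d[a, b] < CLASH_DISTANCE:
                return True
    return False


def _relax(xyz: np.ndarray, bonds: np.ndarray, angles: np.ndarray,
           bond_d0: np.ndarray, angle_d0: np.ndarray,
           nb_pairs: np.ndarray, max_steps: int = 150) -> np.ndarray:
    """Clash-relaxing restrained minimization: soft repulsive term on
    non-bonded pairs plus stiff bond / 1-3 restraints."""

    def fun(x):
        pos = x.reshape(-1, 3)
        grad = np.zeros_like(pos)
        e = 0.0
        if len(nb_pairs):
            eps = np.full(len(nb_pairs), 0.1)
            sig = np.full(len(nb_pairs), 3.0)
            e += _pair_energy_grad(pos, nb_pairs, "lj", eps, sig,
                                   6.0, 1.5, grad)
        e += _pair_energy_grad(pos, bonds, "harm",
                               np.full(len(bonds), 1000.0), bond_d0,
                               0.0, 0.0, grad)
        if len(angles):
            e += _pair_energy_grad(pos, angles, "harm",
                                   np.full(len(angles), 200.0), angle_d0,
                                   0.0, 0.0, grad)
        return e, grad.ravel()

    res = minimize(fun, xyz.ravel(), method="L-BFGS-B", jac=True,
                   options={"maxfun": max_steps, "maxiter": max_steps})
    e0, _ = fun(xyz.ravel())
    return res.x.reshape(-1, 3) if res.fun <= e0 else xyz


def sample_conformers(glycan: Structure, topology: GlycanTopology,
                      n_models: int = 400, effort: float = 16.0,
                      seed: int = 0, sigma_deg: float = SIGMA_BASE_DEG,
                      max_retries: int = 20) -> ConformerEnsemble:
    """Torsion-space perturbation ensemble of a glycan.

    Per member, each glycosidic linkage's phi/psi are shifted by Gaussian
    deviates of width ``sigma_deg * sqrt(effort)``; clashing members are
    relaxed and, if still clashing, resampled (capped retries).  The default
    preset (400 members at 16x effort) is the heaviest sampling schedule;
    ``effort=0`` reproduces the input conformation.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    linkages = _analyze_linkages(glycan, topology)
    heavy0 = glycan.heavy_coords()
    res_of = glycan.heavy_residue_index()
    adjacency = set(topology.linkage_edges)
    bonds_l = build_bond_graph(glycan)
    bonds = np.array(bonds_l, dtype=int).reshape(-1, 2)
    angles = np.array(_one_three(bonds_l), dtype=int).reshape(-1, 2)
    d0 = lambda pr: (np.linalg.norm(heavy0[pr[:, 0]] - heavy0[pr[:, 1]], axis=1)
                     if len(pr) else np.empty(0))
    bond_d0, angle_d0 = d0(bonds), d0(angles)
    # repulsion pairs: between non-adjacent residues only
    nb = [(a, b) for a in range(len(heavy0)) for b in range(a + 1, len(heavy0))
          if res_of[a] != res_of[b]
          and (min(res_of[a], res_of[b]), max(res_of[a], res_of[b]))
          not in adjacency]
    nb_pairs = np.array(nb, dtype=int).reshape(-1, 2)
    sigma = np.deg2rad(sigma_deg) * np.sqrt(max(effort, 0.0))
    rng = np.random.default_rng(seed)
    members = []
    for m in range(n_models):
        ok = False
        for _ in range(max_retries):
            xyz = heavy0.copy()
            for lk in linkages:
                dphi, dpsi = rng.normal(scale=sigma, size=2) if sigma > 0 \
                    else (0.0, 0.0)
                _rotate_subtree(xyz, xyz[lk.c_idx], xyz[lk.o_idx],
                                lk.moving, dphi)
                _rotate_subtree(xyz, xyz[lk.o_idx], xyz[lk.c2_idx],
                                lk.moving, dpsi)
            if _has_clash(xyz, res_of, adjacency):
                xyz = _relax(xyz, bonds, angles, bond_d0, angle_d0, nb_pairs)
            if not _has_clash(xyz, res_of, adjacency):
                ok = True
                break
            if sigma == 0:
                ok = True  # unperturbed input: accept as-is
                break
        if not ok:
            raise RuntimeError(f"member {m}: unresolvable clash after "
                               f"{max_retries} retries")
        member = _with_heavy(glycan, xyz)
        member.model_id = m + 1
        members.append(member)
    return ConformerEnsemble(members, provenance={
        "n_models": n_models, "effort": effort, "seed": seed,
        "sigma_deg": sigma_deg})


def _with_heavy(structure: Structure, heavy_xyz: np.ndarray) -> Structure:
    full = structure.coords()
    full[structure.heavy_mask()] = heavy_xyz
    return structure.with_coords(full)


def _pairwise_rmsd(members: list[Structure]) -> np.ndarray:
    xs = [m.heavy_coords() for m in members]
    n = len(xs)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            _, _, out[k] = kabsch_superpose(xs[i], xs[j])
            k += 1
    return out


def reduce_to_centers(ensemble: ConformerEnsemble,
                      n_clusters: int = 20) -> ConformerEnsemble:
    """Hierarchical-RMSD cluster centers of an ensemble.

    The center of each cluster is the member minimizing the mean RMSD to
    its cluster mates; centers are returned as a (sub-)ensemble, at most
    ``n_clusters`` of them.
    """
    if len(ensemble) < n_clusters:
        raise ValueError("ensemble smaller than the requested cluster count")
    cond = _pairwise_rmsd(ensemble.members)
    if len(cond) and cond.max() < 1e-9:
        warnings.warn("degenerate ensemble (all members identical): "
                      "returning a single center", stacklevel=2)
        return ConformerEnsemble([ensemble.members[0]],
                                 provenance=dict(ensemble.provenance,
                                                 centers=1))
    z = linkage(cond, method="average")
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    sq = np.zeros((len(ensemble), len(ensemble)))
    from scipy.spatial.distance import squareform
    sq = squareform(cond)
    centers = []
    for g in sorted(set(flat)):
        idx = np.where(flat == g)[0]
        mean_r = sq[np.ix_(idx, idx)].mean(axis=1)
        centers.append(ensemble.members[idx[np.argmin(mean_r)]])
    return ConformerEnsemble(centers, provenance=dict(ensemble.provenance,
                                                      centers=n_clusters))


def rmsd_to_reference(ensemble: ConformerEnsemble,
                      reference: Structure) -> np.ndarray:
    """Heavy-atom RMSD of each member to a reference conformation after
    optimal superposition; members and reference are paired by
    (chain, seq_id, atom name)."""
    ref_map = {(r.chain_id, r.seq_id, r.icode, a.name): a.coords
               for r in reference.residues for a in r.heavy_atoms}
    out = np.empty(len(ensemble))
    for k, m in enumerate(ensemble.members):
        mob, ref = [], []
        missing = []
        for r in m.residues:
            for a in r.heavy_atoms:
                key = (r.chain_id, r.seq_id, r.icode, a.name)
                if key not in ref_map:
                    missing.append("/".join(map(str, key)))
                else:
                    mob.append(a.coords)
                    ref.append(ref_map[key])
        if missing:
            raise CorrespondenceError(f"reference lacks atoms: {missing}")
        _, _, out[k] = kabsch_superpose(np.array(mob), np.array(ref))
    ensemble.rmsd_reference = out
    return out
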