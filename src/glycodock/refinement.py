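"""Semi-flexible interface refinement by staged restrained minimization.

Stands in for torsion-angle simulated annealing: two stages of Cartesian
L-BFGS minimization with analytic gradients, in which first the glycan and
the receptor interface side chains, then additionally the interface
backbone, are free to move.  Covalent geometry is maintained by stiff
harmonic restraints on bond lengths and 1-3 distances (the latter acting as
angle restraints for small deviations) toward their starting values; rings
therefore stay closed.  The objective combines the flexref-stage energy
terms (vdW + electrostatics + restraint energy) with these geometry
restraints; non-flexible atoms never move.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .energetics import (NonbondedParams, ScoringWeights, haddock_score,
                         resolve_params, sasa, lennard_jones, coulomb,
                         EnergyReport)
from .restraints import (RestraintSet, IndexedAIR, air_energy_from_coords,
                         index_airs)
from .rigid_docking import DockingModel
from .structures import Structure, select_interface

__all__ = ["FlexSelection", "flex_refine", "build_bond_graph",
           "RefinementError"]

BOND_CUTOFF = 1.8      # A, heavy-atom covalent bond detection
K_BOND = 1000.0        # kcal/(mol A^2)
K_ANGLE = 200.0        # kcal/(mol A^2) on 1-3 distances


class RefinementError(RuntimeError):
    pass


@dataclass
class FlexSelection:
    receptor_flexible: list[tuple]   # residue keys
    ligand_flexible: list[tuple]
    stage: str                       # sidechain | sidechain+backbone


def build_bond_graph(structure: Structure, cutoff: float = BOND_CUTOFF
                     ) -> list[tuple[int, int]]:
    """Heavy-atom bond list (indices into the heavy-atom array) detected by
    distance, both within residues and across glycosidic/peptide links."""
    xyz = structure.heavy_coords()
    pairs = cKDTree(xyz).query_pairs(cutoff)
    return sorted((min(i, j), max(i, j)) for i, j in pairs)


def _one_three(bonds: list[tuple[int, int]]) -> list[tuple[int, int]]:
    nbrs: dict[int, set[int]] = {}
    for i, j in bonds:
        nbrs.setdefault(i, set()).add(j)
        nbrs.setdefault(j, set()).add(i)
    bond_set = set(bonds)
    out = set()
    for center, around in nbrs.items():
        around = sorted(around)
        for a in range(len(around)):
            for b in range(a + 1, len(around)):
                p = (around[a], around[b])
                if p not in bond_set:
                    out.add(p)
    return sorted(out)


def _pair_energy_grad(xyz: np.ndarray, pairs: np.ndarray, kind: str,
                      p1: np.ndarray, p2: np.ndarray,
                      cutoff: float, width: float,
                      grad: np.ndarray) -> float:
    """Accumulate energy and gradient for a list of atom pairs.

    kind 'lj': p1 = epsilon_ij, p2 = sigma_ij (switched LJ)
    kind 'coul': p1 = k_coul * q_i q_j / eps_r, p2 unused (switched)
    kind 'harm': p1 = force constants, p2 = reference distances
    """
    if len(pairs) == 0:
        return 0.0
    d = xyz[pairs[:, 0]] - xyz[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    r = np.maximum(r, 1e-6)
    if kind == "harm":
        dev = r - p2
        e = p1 * dev * dev
        dedr = 2.0 * p1 * dev
        mask = np.ones_like(r, dtype=bool)
    else:
        mask = r < cutoff
        if not mask.any():
            return 0.0
        rm = r[mask]
        x = np.clip((rm - (cutoff - width)) / width, 0.0, 1.0)
        s = 1.0 - x * x * (3.0 - 2.0 * x)
        dsdr = -6.0 * x * (1.0 - x) / width
        if kind == "lj":
            sig, eps = p2[mask], p1[mask]
            sr6 = (sig / rm) ** 6
            e0 = 4.0 * eps * (sr6 * sr6 - sr6)
            de0 = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rm
        else:
            e0 = p1[mask] / rm
            de0 = -p1[mask] / (rm * rm)
        e = e0 * s
        dedr = de0 * s + e0 * dsdr
    total = float(np.sum(e))
    unit = d[mask] / r[mask, None]
    f = dedr[:, None] * unit
    np.add.at(grad, pairs[mask, 0], f)
    np.add.at(grad, pairs[mask, 1], -f)
    return total


def _air_energy_grad(indexed: list[IndexedAIR], xyz: np.ndarray,
                     n_rec: int, params: RestraintSet,
                     grad: np.ndarray) -> float:
    """E_air and gradient over the stacked (receptor + ligand) heavy array."""
    k, sv = params.force_constant, params.switch_violation
    total = 0.0
    for ia in indexed:
        ai = ia.anchor_idx if ia.anchor_on_receptor else ia.anchor_idx + n_rec
        ti = ia.target_idx + n_rec if ia.anchor_on_receptor else ia.target_idx
        a, b = xyz[ai], xyz[ti]
        diff = a[:, None, :] - b[None, :, :]
        d2 = np.sum(diff * diff, axis=-1)
        s6 = np.sum(d2 ** -3)
        d_eff = float(s6 ** (-1.0 / 6.0))
        if ia.lower_bound <= d_eff <= ia.upper_bound:
            continue
        if d_eff > ia.upper_bound:
            v = d_eff - ia.upper_bound
            sign = 1.0
        else:
            v = ia.lower_bound - d_eff
            sign = -1.0
        if v <= sv:
            total += k * v * v
            dedeff = 2.0 * k * v * sign
        else:
            total += k * sv * sv + 2.0 * k * sv * (v - sv)
            dedeff = 2.0 * k * sv * sign
        # d(d_eff)/d(d_ij) = d_eff^7 * d_ij^-7 ; chain through d_ij
        d = np.sqrt(d2)
        dddij = d_eff ** 7 * d ** -7
        f = (dedeff * dddij / d)[:, :, None] * diff
        np.add.at(grad, ai, f.sum(axis=1))
        np.add.at(grad, ti, -f.sum(axis=0))
    return total


class _FlexObjective:
    """Energy + analytic gradient over the free subset of heavy atoms."""

    def __init__(self, receptor: Structure, ligand: Structure,
                 restraints: RestraintSet | None, weights: ScoringWeights,
                 params: NonbondedParams):
        self.params = params
        self.weights = weights
        self.restraints = restraints
        self.rec_terms = resolve_params(receptor, params)
        self.lig_terms = resolve_params(ligand, params)
        self.n_rec = len(self.rec_terms.coords)
        self.xyz0 = np.vstack([self.rec_terms.coords, self.lig_terms.coords])
        self.eps = np.concatenate([self.rec_terms.epsilon, self.lig_terms.epsilon])
        self.sig = np.concatenate([self.rec_terms.sigma, self.lig_terms.sigma])
        self.q = np.concatenate([self.rec_terms.charge, self.lig_terms.charge])
        # covalent topology from the starting geometry
        rec_bonds = build_bond_graph(receptor)
        lig_bonds = [(i + self.n_rec, j + self.n_rec)
                     for i, j in build_bond_graph(ligand)]
        self.bonds = np.array(rec_bonds + lig_bonds, dtype=int).reshape(-1, 2)
        self.angles = np.array(_one_three(rec_bonds + lig_bonds),
                               dtype=int).reshape(-1, 2)
        d0 = lambda pairs: np.linalg.norm(
            self.xyz0[pairs[:, 0]] - self.xyz0[pairs[:, 1]], axis=1)
        self.bond_d0 = d0(self.bonds) if len(self.bonds) else np.empty(0)
        self.angle_d0 = d0(self.angles) if len(self.angles) else np.empty(0)
        self.indexed = (index_airs(restraints, receptor, ligand)
                        if restraints else [])
        self._nb_pairs = self._nonbonded_pairs()

    def _nonbonded_pairs(self) -> np.ndarray:
        """Intermolecular pairs plus intra-ligand pairs separated by more
        than three bonds; intra-receptor interactions are carried entirely
        by the geometry restraints."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.xyz0)))
        g.add_edges_from(map(tuple, self.bonds))
        near = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
        cut = self.params.cutoff + 3.0  # static neighbour list with margin
        pairs = cKDTree(self.xyz0).query_pairs(cut)
        keep = []
        for i, j in pairs:
            i, j = min(i, j), max(i, j)
            both_rec = j < self.n_rec
            both_lig = i >= self.n_rec
            if both_rec:
                continue
            if both_lig and j in near.get(i, ()):
                continue
            keep.append((i, j))
        return np.array(sorted(keep), dtype=int).reshape(-1, 2)

    def energy_grad(self, xyz: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(xyz)
        p = self.params
        i, j = self._nb_pairs[:, 0], self._nb_pairs[:, 1]
        eps_ij = np.sqrt(self.eps[i] * self.eps[j])
        sig_ij = 0.5 * (self.sig[i] + self.sig[j])
        qq = 332.0636 * self.q[i] * self.q[j] / p.relative_permittivity
        g_lj = np.zeros_like(xyz)
        e_lj = _pair_energy_grad(xyz, self._nb_pairs, "lj", eps_ij, sig_ij,
                                 p.cutoff, p.switch_width, g_lj)
        g_coul = np.zeros_like(xyz)
        e_coul = _pair_energy_grad(xyz, self._nb_pairs, "coul", qq, qq,
                                   p.cutoff, p.switch_width, g_coul)
        e = self.weights.w_vdW * e_lj + self.weights.w_elec * e_coul
        grad += self.weights.w_vdW * g_lj + self.weights.w_elec * g_coul
        e_geom = 0.0
        if len(self.bonds):
            e_geom += _pair_energy_grad(
                xyz, self.bonds, "harm",
                np.full(len(self.bonds), K_BOND), self.bond_d0,
                0.0, 0.0, grad)
        if len(self.angles):
            e_geom += _pair_energy_grad(
                xyz, self.angles, "harm",
                np.full(len(self.angles), K_ANGLE), self.angle_d0,
                0.0, 0.0, grad)
        e += e_geom
        if self.indexed and self.weights.w_air:
            ag = np.zeros_like(xyz)
            e_air = _air_energy_grad(self.indexed, xyz, self.n_rec,
                                     self.restraints, ag)
            e += self.weights.w_air * e_air
            grad += self.weights.w_air * ag
        return e, grad


def _interface_keys(receptor: Structure, ligand: Structure,
                    cutoff: float) -> list[tuple]:
    iface, _ = select_interface(receptor, ligand, cutoff=cutoff)
    return [r.key for r in iface]


def _free_heavy_indices(receptor: Structure, ligand: Structure,
                        flex_keys: list[tuple], include_backbone: bool,
                        n_rec: int) -> np.ndarray:
    free = []
    k = 0
    flex = set(flex_keys)
    for r in receptor.residues:
        for a in r.heavy_atoms:
            if r.key in flex and (include_backbone or not
                                  a.name in ("N", "CA", "C", "O", "OXT")):
                free.append(k)
            k += 1
    free.extend(range(n_rec, n_rec + len(ligand.heavy_coords())))
    return np.array(free, dtype=int)


def _rebuild(structure: Structure, heavy_xyz: np.ndarray) -> Structure:
    """New structure with heavy-atom coordinates replaced, hydrogens kept."""
    full = structure.coords()
    mask = structure.heavy_mask()
    full[mask] = heavy_xyz
    return structure.with_coords(full)


def flex_refine(receptor: Structure, model: DockingModel,
                restraints: RestraintSet | None = None,
                weights: ScoringWeights | None = None,
                params: NonbondedParams | None = None,
                flex_cutoff: float = 5.0,
                steps_per_stage: int = 500,
                sasa_points: int = 240) -> DockingModel:
    """Two-stage restrained interface refinement of one docking model.

    Stage 1 frees the glycan and receptor interface side chains; stage 2
    additionally frees the interface backbone.  The refined model is
    re-scored with the flexref weight set.  If the minimization distorts any
    bond by more than 0.5 A the refinement is rejected and the input model
    is returned flagged 'refinement-rejected'.
    """
    weights = weights or ScoringWeights.flexref()
    params = params or NonbondedParams()
    rec = receptor if model.receptor is None else model.receptor
    lig = model.ligand
    obj = _FlexObjective(rec, lig, restraints, weights, params)
    flex_keys = _interface_keys(rec, lig, flex_cutoff)
    selection = FlexSelection(
        receptor_flexible=flex_keys,
        ligand_flexible=[r.key for r in lig.residues],
        stage="sidechain")
    xyz = obj.xyz0.copy()
    for stage_backbone in (False, True):
        if steps_per_stage <= 0:
            break
        selection.stage = "sidechain+backbone" if stage_backbone else "sidechain"
        free = _free_heavy_indices(rec, lig, selection.receptor_flexible,
                                   stage_backbone, obj.n_rec)

        def fun(x_flat: np.ndarray):
            pos = xyz.copy()
            pos[free] = x_flat.reshape(-1, 3)
            e, g = obj.energy_grad(pos)
            return e, g[free].ravel()

        res = minimize(fun, xyz[free].ravel(), method="L-BFGS-B", jac=True,
                       options={"maxfun": steps_per_stage, "maxiter":
                                steps_per_stage})
        e_new = res.fun
        e_old, _ = obj.energy_grad(xyz)
        if np.isfinite(e_new) and e_new <= e_old:
            xyz[free] = res.x.reshape(-1, 3)
    # covalent-geometry guard
    if len(obj.bonds):
        d = np.linalg.norm(xyz[obj.bonds[:, 0]] - xyz[obj.bonds[:, 1]], axis=1)
        if np.max(np.abs(d - obj.bond_d0)) > 0.5:
            return replace(model, flags=model.flags + ["refinement-rejected"])
    new_rec = _rebuild(rec, xyz[:obj.n_rec])
    new_lig = _rebuild(lig, xyz[obj.n_rec:])
    report = _rescore(new_rec, new_lig, obj, xyz, params, sasa_points)
    score = haddock_score(report, weights)
    return replace(model, ligand=new_lig, receptor=new_rec, energies=report,
                   score=score, stage="flexref")


def _rescore(rec: Structure, lig: Structure, obj: _FlexObjective,
             xyz: np.ndarray, params: NonbondedParams,
             sasa_points: int) -> EnergyReport:
    rec_terms = resolve_params(rec, params)
    lig_terms = resolve_params(lig, params)
    e_vdw = lennard_jones(rec_terms, lig_terms, params)
    e_elec = coulomb(rec_terms, lig_terms, params)
    e_air = (air_energy_from_coords(obj.indexed, rec_terms.coords,
                                    lig_terms.coords, obj.restraints)
             if obj.indexed else 0.0)
    free_a = sasa(rec_terms.coords, rec_terms.radii, n_points=sasa_points)
    free_b = sasa(lig_terms.coords, lig_terms.radii, n_points=sasa_points)
    joint = sasa(np.vstack([rec_terms.coords, lig_terms.coords]),
                 np.concatenate([rec_terms.radii, lig_terms.radii]),
                 n_points=sasa_points)
    na = len(rec_terms.coords)
    e_bsa = max(float(free_a.sum() + free_b.sum() - joint.sum()), 0.0)
    e_dslv = float(np.dot(rec_terms.solv, free_a - joint[:na])
                   + np.dot(lig_terms.solv, free_b - joint[na:]))
    return EnergyReport(e_vdw, e_elec, e_dslv, e_bsa, e_air)
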