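"""Synthetic toy protein-glycan complexes and decoy sets.

The generator builds desk-scale complexes with planted, known properties so
the whole pipeline (restraints, energies, docking, clustering, evaluation)
can be exercised without external data:

* the glycan is a chain of 2-7 idealized six-membered pseudo-pyranose rings
  (hexagonal C5O skeleton with exocyclic oxygens), linked through anomeric
  C1 -> O4 contacts at glycosidic bond length, optionally with one branch
  through O2 (a degree-3 unit);
* the receptor is a concave cradle of pseudo amino-acid residues (backbone
  N/CA/C/O plus CB/CG side chain) wrapped around the lower half of the
  glycan, with side-chain tips ~3.5 A from the glycan surface, so the bound
  pose has a genuine interface and no steric clash.

Pseudo-atom chemistry (generic C/N/O classes) is intentional: the fixtures
test mechanics, not force-field realism.  Decoys are built by a screw-motion
perturbation of the bound glycan, scaled by bisection until the realized
IL-RMSD matches a requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import EnergyReport
from .evaluation import Quality, classify_quality, il_rmsd
from .rigid_docking import DockingModel, Pose
from .structures import (Atom, GlycanTopology, Residue, ResidueKind, Structure,
                         build_glycan_topology)
from .structures import Role

__all__ = ["ToyComplex", "DecoySet", "make_toy_complex", "make_decoys"]

_SUGAR_NAMES = ["GLC", "GAL", "MAN", "FUC", "NAG", "BGC", "BMA"]

_RING_NAMES = ["C1", "C2", "C3", "C4", "C5", "O5"]
_RING_RADIUS = 1.5       # regular hexagon => ring bond length 1.5 A
_EXO_BOND = 1.43         # exocyclic / glycosidic C-O bond length


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _ring_template() -> dict[str, np.ndarray]:
    """Idealized pyranose-like unit in its local frame (ring in xy plane)."""
    atoms = {}
    for i, name in enumerate(_RING_NAMES):
        ang = np.deg2rad(60.0 * i)
        atoms[name] = _RING_RADIUS * np.array([np.cos(ang), np.sin(ang), 0.0])
    # exocyclic oxygens: radial from their ring carbon, slightly out of plane
    for cname, oname in (("C1", "O1"), ("C2", "O2"), ("C4", "O4")):
        c = atoms[cname]
        radial = c / np.linalg.norm(c)
        direction = 0.9 * radial + 0.45 * np.array([0.0, 0.0, 1.0])
        direction /= np.linalg.norm(direction)
        atoms[oname] = c + _EXO_BOND * direction
    return atoms


def _make_residue(chain: str, seq: int, name: str, placed: dict[str, np.ndarray],
                  drop: set[str], serial_start: int) -> Residue:
    atoms = []
    serial = serial_start
    for aname in _RING_NAMES + ["O1", "O2", "O4"]:
        if aname in drop or aname not in placed:
            continue
        atoms.append(Atom(serial, aname, aname[0], placed[aname].copy()))
        serial += 1
    return Residue(chain, seq, name, atoms, kind=ResidueKind.MONOSACCHARIDE)


def _build_glycan(n_units: int, branched: bool, rng: np.random.Generator
                  ) -> Structure:
    template = _ring_template()
    n_chain = n_units - 1 if branched else n_units
    rotations, offsets = [], []
    pos = np.zeros(3)
    placed_residues: list[dict[str, np.ndarray]] = []
    for k in range(n_chain):
        zig = np.deg2rad(18.0 if k % 2 == 0 else -18.0)
        twist = np.deg2rad(25.0 * k + rng.uniform(-8.0, 8.0))
        rot = _rot_z(zig) @ _rot_x(twist)
        if k == 0:
            offset = np.zeros(3)
        else:
            # place this unit so its O4 sits one glycosidic bond beyond the
            # previous unit's anomeric C1
            prev_c1 = placed_residues[-1]["C1"]
            d = rot @ np.array([1.0, 0.0, 0.0])
            target_o4 = prev_c1 + _EXO_BOND * d
            offset = target_o4 - rot @ template["O4"]
        placed_residues.append({n: rot @ x + offset for n, x in template.items()})
        rotations.append(rot)
        offsets.append(offset)
    branch_at = None
    if branched:
        # attach one unit through O2 of a mid-chain residue (degree-3 unit)
        branch_at = n_chain // 2
        core = placed_residues[branch_at]
        d = core["O2"] - core["C2"]
        d /= np.linalg.norm(d)
        target_c1 = core["O2"] + _EXO_BOND * d
        # orient the branch ring to extend away from the core: map the local
        # C1->ring-center direction (-x) onto d, with a fixed roll
        from scipy.spatial.transform import Rotation

        align, _ = Rotation.align_vectors([-d], [[1.0, 0.0, 0.0]])
        rot = align.as_matrix() @ _rot_z(np.deg2rad(30.0))
        offset = target_c1 - rot @ template["C1"]
        placed_residues.append({n: rot @ x + offset for n, x in template.items()})

    residues = []
    serial = 1
    for k, placed in enumerate(placed_residues):
        drop = set()
        if k < n_chain - 1 or (branched and k == len(placed_residues) - 1):
            drop.add("O1")  # anomeric O replaced by the glycosidic linkage
        res = _make_residue("B", k + 1, _SUGAR_NAMES[k % len(_SUGAR_NAMES)],
                            placed, drop, serial)
        serial += len(res.atoms)
        residues.append(res)
    return Structure(residues, role=Role.LIGAND)


def _build_receptor(glycan: Structure, rng: np.random.Generator) -> Structure:
    """Concave cradle of pseudo-residues under the glycan (-z hemisphere)."""
    gx = glycan.heavy_coords()
    lo, hi = gx[:, 0].min(), gx[:, 0].max()
    n_axial = max(3, int(np.ceil((hi - lo) / 3.0)) + 1)
    azimuths = np.deg2rad([210.0, 255.0, 300.0, 345.0])
    residues = []
    serial = 1
    seq = 1
    axial = np.array([1.0, 0.0, 0.0])
    for s in np.linspace(lo, hi, n_axial):
        near = gx[np.abs(gx[:, 0] - s) < 2.5]
        if near.size == 0:
            near = gx
        for az in azimuths:
            u = np.array([0.0, np.cos(az), np.sin(az)])
            # radial extent of the glycan in this slab along u
            r_gly = max(float(np.max(near[:, 1:] @ u[1:])), 0.0)
            base = np.array([s, 0.0, 0.0]) + u * (r_gly + 3.5)
            # push outward until clash-free against the whole glycan
            for _ in range(40):
                if np.min(np.linalg.norm(gx - base, axis=1)) >= 3.2:
                    break
                base = base + 0.25 * u
            jitter = rng.normal(scale=0.12, size=3)
            cg = base + jitter
            cb = cg + 1.5 * u
            ca = cb + 1.5 * u
            n_at = ca + 1.4 * axial + 0.3 * u
            c_at = ca - 1.4 * axial + 0.3 * u
            o_at = c_at + 1.2 * u
            coords = {"N": n_at, "CA": ca, "C": c_at, "O": o_at,
                      "CB": cb, "CG": cg}
            atoms = [Atom(serial + i, name, name[0], xyz)
                     for i, (name, xyz) in enumerate(coords.items())]
            serial += len(atoms)
            residues.append(Residue("A", seq, "ALA", atoms,
                                    kind=ResidueKind.AMINO_ACID))
            seq += 1
    return Structure(residues, role=Role.RECEPTOR)


@dataclass
class ToyComplex:
    receptor: Structure
    glycan: Structure           # bound reference pose
    topology: GlycanTopology
    seed: int

    @property
    def reference(self) -> tuple[Structure, Structure]:
        return (self.receptor, self.glycan)


def make_toy_complex(n_units: int = 3, branched: bool = False,
                     seed: int = 0) -> ToyComplex:
    """Deterministic toy complex with a planted bound pose.

    The bound pose is guaranteed to have at least three receptor residues
    within 3.9 A of the glycan and no heavy-atom contact below 2.2 A.
    """
    if not 2 <= n_units <= 7:
        raise ValueError("n_units must be in [2, 7]")
    if branched and n_units < 4:
        # a degree-3 linkage node needs a chain neighbour on both sides
        # plus the branch itself
        raise ValueError("a branched glycan needs at least 4 units")
    rng = np.random.default_rng(seed)
    glycan = _build_glycan(n_units, branched, rng)
    receptor = _build_receptor(glycan, rng)
    toy = ToyComplex(receptor, glycan, build_glycan_topology(glycan), seed)
    _validate_toy(toy)
    return toy


def _validate_toy(toy: ToyComplex) -> None:
    from .structures import select_interface
    from scipy.spatial.distance import cdist

    d = cdist(toy.receptor.heavy_coords(), toy.glycan.heavy_coords())
    if d.min() < 2.2:
        raise RuntimeError(f"toy bound pose has a clash ({d.min():.2f} A)")
    iface, _ = select_interface(toy.receptor, toy.glycan, cutoff=3.9)
    if len(iface) < 3:
        raise RuntimeError("toy bound pose interface smaller than 3 residues")
    if len(toy.topology.linkage_edges) != toy.topology.n_units - 1:
        raise RuntimeError("toy glycan linkage graph is not a tree")


@dataclass
class DecoySet:
    models: list[DockingModel]
    truth: dict[int, Quality]   # model_id -> planted tier
    requested: dict[int, float]
    realized: dict[int, float]


def _screw_coords(xyz: np.ndarray, centroid: np.ndarray, axis: np.ndarray,
                  tdir: np.ndarray, s: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    if s == 0.0:
        return xyz.copy()
    rot = Rotation.from_rotvec(axis * 0.25 * s)
    return rot.apply(xyz - centroid) + centroid + tdir * 0.8 * s


def make_decoys(toy: ToyComplex, requested_il_rmsds: list[float],
                seed: int = 0, scores: list[float] | None = None,
                tolerance: float = 0.1,
                ensure_clash: bool = False) -> DecoySet:
    """Decoys at requested IL-RMSDs via a bisected screw motion.

    Each decoy applies a rigid rotation+translation (screw motion, random
    axis per decoy) to the bound glycan, with the motion amplitude bisected
    until the realized IL-RMSD is within ``tolerance`` of the request.
    Scores are plantable to impose any ranking (default: rank = input order).
    With ``ensure_clash`` the screw axis is redrawn until the decoy presses
    into the receptor (a heavy-atom contact below 2.8 A), planting a steric
    clash at the requested displacement.
    """
    import warnings

    from .energetics import NonbondedParams, lennard_jones, resolve_params

    rng = np.random.default_rng(seed)
    gx = toy.glycan.coords()
    centroid = toy.glycan.heavy_coords().mean(axis=0)
    nb = NonbondedParams()
    rec_terms = resolve_params(toy.receptor, nb)
    lig_terms = resolve_params(toy.glycan, nb)
    models, truth, req_map, real_map = [], {}, {}, {}
    for i, target in enumerate(requested_il_rmsds):
        if target < 0:
            raise ValueError("requested IL-RMSD must be >= 0")
        for _attempt in range(30):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            tdir = rng.normal(size=3)
            tdir /= np.linalg.norm(tdir)

            def realized(s: float) -> float:
                moved = toy.glycan.with_coords(
                    _screw_coords(gx, centroid, axis, tdir, s))
                return il_rmsd(toy.receptor, moved, toy.receptor, toy.glycan)

            if target == 0.0:
                s = 0.0
            else:
                lo, hi = 0.0, 1.0
                for _ in range(40):
                    if realized(hi) >= target:
                        break
                    hi *= 2.0
                else:
                    warnings.warn(f"decoy {i}: request {target} A unreachable;"
                                  " best effort", stacklevel=2)
                for _ in range(60):
                    s = 0.5 * (lo + hi)
                    r = realized(s)
                    if abs(r - target) <= tolerance * 0.5:
                        break
                    if r < target:
                        lo = s
                    else:
                        hi = s
                else:
                    s = 0.5 * (lo + hi)
            moved_xyz = _screw_coords(gx, centroid, axis, tdir, s)
            heavy = moved_xyz[toy.glycan.heavy_mask()]
            if (not ensure_clash or target == 0.0
                    or lennard_jones(rec_terms, lig_terms, nb,
                                     coords_lig=heavy) > 5.0):
                break
        else:
            warnings.warn(f"decoy {i}: could not plant a clash", stacklevel=2)
        moved = toy.glycan.with_coords(moved_xyz)
        real = il_rmsd(toy.receptor, moved, toy.receptor, toy.glycan)
        score = scores[i] if scores is not None else float(i)
        model = DockingModel(
            pose=Pose(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3)),
            ligand=moved, energies=EnergyReport(), score=score,
            model_id=i, seed=seed, stage="decoy")
        models.append(model)
        truth[i] = classify_quality(real)
        req_map[i] = float(target)
        real_map[i] = real
    return DecoySet(models, truth, req_map, real_map)
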