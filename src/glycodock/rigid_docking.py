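"""Restraint-driven rigid-body docking.

Each docking model starts from a fully randomized ligand orientation placed
outside the receptor and is relaxed by direct-search minimization (Nelder-
Mead over the six rigid degrees of freedom) of the restraint plus
intermolecular energy.  Surface terms (BSA, desolvation) are computed once
per final pose for scoring, not inside the minimizer.  Every model draws an
independent randomly-discarded restraint subset (50% by default), emulating
noisy interface information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .energetics import (EnergyReport, NonbondedParams, ScoringWeights,
                         coulomb, haddock_score, lennard_jones, resolve_params, sasa)
from .restraints import (RestraintSet, air_energy_from_coords, index_airs,
                         random_discard)
from .structures import Structure

__all__ = ["Pose", "DockingModel", "SamplingConfig", "DockingError",
           "randomize_pose", "rigid_minimize", "generate_models", "models_table"]

log = logging.getLogger(__name__)


class DockingError(RuntimeError):
    pass


@dataclass
class Pose:
    """Rigid transform applied to the ligand about its original centroid."""

    quaternion: np.ndarray   # (4,) scalar-last, unit norm
    translation: np.ndarray  # (3,) A

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-12:
            q = q / n
        self.quaternion = q
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        rot = Rotation.from_quat(self.quaternion)
        return rot.apply(coords - pivot) + pivot + self.translation

    def compose_delta(self, rotvec: np.ndarray, dtrans: np.ndarray) -> "Pose":
        """New pose: extra rotation (rotation-vector) and translation applied
        on top of this one."""
        r = Rotation.from_rotvec(rotvec) * Rotation.from_quat(self.quaternion)
        return Pose(r.as_quat(), self.translation + np.asarray(dtrans))


@dataclass
class DockingModel:
    pose: Pose
    ligand: Structure            # posed ligand (all atoms transformed)
    energies: EnergyReport
    score: float
    model_id: int
    seed: int
    source_conformer: int = 0
    stage: str = "rigidbody"
    receptor: Structure | None = None  # set by refinement stages
    flags: list[str] = field(default_factory=list)


@dataclass
class SamplingConfig:
    n_models: int = 1000
    n_models_per_conformer: int = 200
    seed: int = 0
    start_separation: float = 3.0  # A beyond the bounding spheres
    discard_fraction: float = 0.5
    max_iter: int = 300
    sasa_points: int = 240
    retry_limit: int = 10

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.n_models_per_conformer < 1:
            raise ValueError("model counts must be >= 1")


def randomize_pose(receptor: Structure, ligand: Structure, seed: int,
                   start_separation: float = 3.0) -> Pose:
    """Uniformly random orientation; centroid placed on a random direction
    from the receptor at the sum of bounding radii plus a separation margin,
    so starting poses are clash-free."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    dist = receptor.bounding_radius() + ligand.bounding_radius() + start_separation
    translation = receptor.centroid() + dist * u - ligand.centroid()
    return Pose(q, translation)


class _RigidObjective:
    """Minimization objective over (rotvec, translation) deltas from a start
    pose: w_air*E_air + w_vdW*E_vdW + w_elec*E_elec on heavy atoms."""

    def __init__(self, receptor: Structure, ligand: Structure,
                 restraints: RestraintSet, weights: ScoringWeights,
                 params: NonbondedParams, start: Pose):
        self.params = params
        self.weights = weights
        self.restraints = restraints
        self.rec_terms = resolve_params(receptor, params)
        self.lig_terms = resolve_params(ligand, params)
        self.lig_heavy0 = ligand.heavy_coords()
        self.pivot = self.lig_heavy0.mean(axis=0)
        self.indexed = index_airs(restraints, receptor, ligand)
        self.start = start

    def posed_heavy(self, x: np.ndarray) -> np.ndarray:
        pose = self.start.compose_delta(x[:3], x[3:])
        return pose.apply(self.lig_heavy0, self.pivot)

    def __call__(self, x: np.ndarray) -> float:
        lig_xyz = self.posed_heavy(x)
        e = 0.0
        if self.weights.w_air:
            e += self.weights.w_air * air_energy_from_coords(
                self.indexed, self.rec_terms.coords, lig_xyz, self.restraints)
        if self.weights.w_vdW:
            e += self.weights.w_vdW * lennard_jones(
                self.rec_terms, self.lig_terms, self.params, coords_lig=lig_xyz)
        if self.weights.w_elec:
            e += self.weights.w_elec * coulomb(
                self.rec_terms, self.lig_terms, self.params, coords_lig=lig_xyz)
        return e if np.isfinite(e) else 1e12


def _final_report(obj: _RigidObjective, lig_xyz: np.ndarray,
                  sasa_points: int) -> EnergyReport:
    rec, lig = obj.rec_terms, obj.lig_terms
    e_vdw = lennard_jones(rec, lig, obj.params, coords_lig=lig_xyz)
    e_elec = coulomb(rec, lig, obj.params, coords_lig=lig_xyz)
    e_air = air_energy_from_coords(obj.indexed, rec.coords, lig_xyz, obj.restraints)
    free_a = sasa(rec.coords, rec.radii, n_points=sasa_points)
    free_b = sasa(lig_xyz, lig.radii, n_points=sasa_points)
    joint = sasa(np.vstack([rec.coords, lig_xyz]),
                 np.concatenate([rec.radii, lig.radii]), n_points=sasa_points)
    na = len(rec.coords)
    e_bsa = max(float(free_a.sum() + free_b.sum() - joint.sum()), 0.0)
    e_dslv = float(np.dot(rec.solv, free_a - joint[:na])
                   + np.dot(lig.solv, free_b - joint[na:]))
    return EnergyReport(e_vdw, e_elec, e_dslv, e_bsa, e_air)


def rigid_minimize(receptor: Structure, ligand: Structure, pose: Pose,
                   restraints: RestraintSet, weights: ScoringWeights,
                   max_iter: int = 300,
                   params: NonbondedParams | None = None,
                   sasa_points: int = 240,
                   model_id: int = 0, seed: int = 0,
                   source_conformer: int = 0) -> DockingModel:
    """Direct-search rigid-body minimization from a starting pose.

    Two Nelder-Mead passes are run: a coarse one with a wide initial simplex
    (0.4 rad / 2 A) followed by a polishing pass (0.1 rad / 0.5 A).  The
    returned model carries the full five-term energy report and stage score.
    """
    params = params or NonbondedParams()
    obj = _RigidObjective(receptor, ligand, restraints, weights, params, pose)
    x = np.zeros(6)
    if not np.isfinite(obj(x)):
        raise DockingError("non-finite energy at the starting pose")
    # approach scan: slide the ligand along the line toward the receptor
    # centre and keep the best point, so the local search starts in contact
    start_centroid = pose.apply(obj.lig_heavy0, obj.pivot).mean(axis=0)
    to_rec = receptor.centroid() - start_centroid
    d0 = np.linalg.norm(to_rec)
    u = to_rec / d0
    for t in np.linspace(0.0, d0 + 4.0, 60):
        cand = np.concatenate([np.zeros(3), t * u])
        if obj(cand) < obj(x):
            x = cand
    for scale_r, scale_t, frac in ((0.4, 2.0, 0.6), (0.1, 0.5, 0.25),
                                   (0.03, 0.15, 0.15)):
        simplex = np.tile(x, (7, 1))
        for i in range(3):
            simplex[i + 1, i] += scale_r
            simplex[i + 4, i + 3] += scale_t
        res = minimize(obj, x, method="Nelder-Mead",
                       options={"initial_simplex": simplex,
                                "maxiter": max(1, int(max_iter * frac)),
                                "xatol": 1e-3, "fatol": 1e-4})
        if obj(res.x) <= obj(x):
            x = res.x
    final_pose = pose.compose_delta(x[:3], x[3:])
    posed = ligand.with_coords(final_pose.apply(ligand.coords(),
                                                obj.pivot))
    report = _final_report(obj, posed.heavy_coords(), sasa_points)
    score = haddock_score(report, weights)
    return DockingModel(final_pose, posed, report, score, model_id=model_id,
                        seed=seed, source_conformer=source_conformer)


def generate_models(receptor: Structure,
                    ligand: Structure | list[Structure],
                    restraints: RestraintSet,
                    config: SamplingConfig,
                    weights: ScoringWeights,
                    params: NonbondedParams | None = None) -> list[DockingModel]:
    """Generate a rigid-body model set, sorted by score ascending.

    A single ligand yields ``n_models`` models; an ensemble yields
    ``n_models_per_conformer`` per member.  Each model has its own seed
    (derived from the run seed) controlling both the restraint discard and
    the random start, so runs are exactly reproducible.
    """
    params = params or NonbondedParams()
    conformers = ligand if isinstance(ligand, list) else [ligand]
    if isinstance(ligand, list):
        per = [config.n_models_per_conformer] * len(conformers)
    else:
        per = [config.n_models]
    total = sum(per)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        total * (config.retry_limit + 1)) % (2 ** 31)
    models: list[DockingModel] = []
    k = 0
    mid = 0
    for ci, (conf, n) in enumerate(zip(conformers, per)):
        for _ in range(n):
            model = None
            for _attempt in range(config.retry_limit + 1):
                s = int(seeds[k]); k += 1
                subset = random_discard(restraints, config.discard_fraction, seed=s)
                start = randomize_pose(receptor, conf, seed=s,
                                       start_separation=config.start_separation)
                try:
                    model = rigid_minimize(
                        receptor, conf, start, subset, weights,
                        max_iter=config.max_iter, params=params,
                        sasa_points=config.sasa_points,
                        model_id=mid, seed=s, source_conformer=ci)
                    break
                except DockingError:
                    log.warning("model %d: non-finite start, resampling", mid)
            if model is None:
                raise DockingError(f"model {mid}: all {config.retry_limit + 1} "
                                   "starts failed")
            models.append(model)
            mid += 1
    models.sort(key=lambda m: (m.score, m.model_id))
    return models


def models_table(models: list[DockingModel]):
    """Per-model energy breakdown and score as a pandas DataFrame."""
    import pandas as pd

    rows = [{
        "model_id": m.model_id, "stage": m.stage, "score": m.score,
        "E_vdW": m.energies.E_vdW, "E_elec": m.energies.E_elec,
        "E_desolv": m.energies.E_desolv, "E_BSA": m.energies.E_BSA,
        "E_air": m.energies.E_air, "seed": m.seed,
        "source_conformer": m.source_conformer,
        "flags": ";".join(m.flags),
    } for m in models]
    return pd.DataFrame(rows)
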