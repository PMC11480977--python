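"""Ambiguous interaction restraints (AIRs) and their energy.

An AIR ties one *active* residue (the anchor) to a set of partner residues
(the partner's active plus passive set): the restraint is satisfied when the
effective distance between the anchor's heavy atoms and the pooled target
heavy atoms falls inside the bounds.  The effective distance uses the
r^-6-sum convention, so approaching any one target satisfies the restraint.
The energy is flat inside the bounds, harmonic for short violations and
linear beyond a switch point (continuous value and slope), which keeps
forces bounded during minimization.

Two scenarios are supported: ``ti-aa`` (true interface, active on both
partners) and ``tip-ap`` (true interface active on the protein only, the
whole glycan passive).  Half of the AIRs are, by default, randomly discarded
per docking model to emulate noisy interface information.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structures import Residue, Structure, select_interface

__all__ = [
    "Scenario",
    "AIR",
    "RestraintSet",
    "RestraintError",
    "build_airs",
    "effective_distance",
    "air_energy",
    "total_air_energy",
    "random_discard",
]


class Scenario(enum.Enum):
    TI_AA = "ti-aa"
    TIP_AP = "tip-ap"


class RestraintError(ValueError):
    """Restraint cannot be built or resolved against a complex."""


ResidueRef = tuple[str, str, int, str]  # (partner role, chain, seq_id, icode)


def _ref(role: str, res: Residue) -> ResidueRef:
    return (role, res.chain_id, res.seq_id, res.icode)


@dataclass(frozen=True)
class AIR:
    """One ambiguous restraint: anchor residue vs a pool of partner residues."""

    anchor: ResidueRef
    targets: tuple[ResidueRef, ...]
    upper_bound: float = 2.0
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise RestraintError("AIR with empty target set")
        if not (0.0 <= self.lower_bound <= self.upper_bound):
            raise RestraintError("require 0 <= lower_bound <= upper_bound")


@dataclass
class RestraintSet:
    airs: list[AIR]
    scenario: Scenario
    force_constant: float = 50.0  # kcal/(mol A^2)
    switch_violation: float = 1.0  # A, harmonic -> linear transition

    def __post_init__(self) -> None:
        if self.force_constant <= 0 or self.switch_violation <= 0:
            raise RestraintError("force_constant and switch_violation must be > 0")

    def __len__(self) -> int:
        return len(self.airs)


def build_airs(
    receptor: Structure,
    ligand: Structure,
    scenario: Scenario | str = Scenario.TI_AA,
    interface_cutoff: float = 3.9,
    reference: tuple[Structure, Structure] | None = None,
    active_receptor: list[Residue] | None = None,
    active_ligand: list[Residue] | None = None,
    upper_bound: float = 2.0,
    lower_bound: float = 0.0,
    force_constant: float = 50.0,
    switch_violation: float = 1.0,
) -> RestraintSet:
    """Derive the AIR list for a docking scenario.

    The true interface is taken from ``reference`` (a bound receptor/ligand
    pair) at ``interface_cutoff``, unless explicit active residue lists are
    given.  In ``ti-aa`` each active residue on either partner anchors one
    AIR whose targets are the partner's active set; in ``tip-ap`` only
    protein actives anchor AIRs and every glycan residue is a passive target.
    """
    if isinstance(scenario, str):
        scenario = Scenario(scenario)
    if active_receptor is None or active_ligand is None:
        ref_r, ref_l = reference if reference is not None else (receptor, ligand)
        sel_r, sel_l = select_interface(ref_r, ref_l, cutoff=interface_cutoff)
        active_receptor = active_receptor or sel_r
        active_ligand = active_ligand or sel_l
    if not active_receptor:
        raise RestraintError("no active residues on the protein receptor")

    rec_refs = tuple(_ref("receptor", r) for r in active_receptor)
    airs: list[AIR] = []
    if scenario is Scenario.TI_AA:
        lig_refs = tuple(_ref("ligand", r) for r in active_ligand)
        if not lig_refs:
            raise RestraintError("ti-aa scenario requires active glycan residues")
        for r in rec_refs:
            airs.append(AIR(r, lig_refs, upper_bound, lower_bound))
        for l in lig_refs:
            airs.append(AIR(l, rec_refs, upper_bound, lower_bound))
    else:  # tip-ap: protein actives anchor; all glycan residues passive targets
        all_lig = tuple(_ref("ligand", r) for r in ligand.residues)
        for r in rec_refs:
            airs.append(AIR(r, all_lig, upper_bound, lower_bound))
    return RestraintSet(airs, scenario, force_constant, switch_violation)


def effective_distance(anchor_xyz: np.ndarray, target_xyz: np.ndarray) -> float:
    """d_eff = (sum_ij d_ij^-6)^(-1/6) over all anchor-target atom pairs.

    Always <= the minimum pairwise distance; dominated by the closest pairs.
    """
    a = np.asarray(anchor_xyz, dtype=float).reshape(-1, 3)
    b = np.asarray(target_xyz, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise RestraintError("empty atom set in effective distance")
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    if np.any(d2 == 0.0):
        raise RestraintError("coincident atoms (zero distance) in effective distance")
    return float(np.sum(d2 ** -3) ** (-1.0 / 6.0))


def _flat_bottom(v: float, k: float, sv: float) -> float:
    # v is the (positive) violation beyond a bound
    if v <= 0:
        return 0.0
    if v <= sv:
        return k * v * v
    # linear continuation matching value and slope at v = sv
    return k * sv * sv + 2.0 * k * sv * (v - sv)


def air_energy(d_eff: float, restraint: AIR, params: RestraintSet) -> float:
    """Flat-bottom restraint energy of one AIR at effective distance d_eff."""
    if d_eff <= 0:
        raise RestraintError("effective distance must be positive")
    k, sv = params.force_constant, params.switch_violation
    if d_eff > restraint.upper_bound:
        return _flat_bottom(d_eff - restraint.upper_bound, k, sv)
    if d_eff < restraint.lower_bound:
        return _flat_bottom(restraint.lower_bound - d_eff, k, sv)
    return 0.0


def _collect_heavy(structure: Structure, ref: ResidueRef) -> np.ndarray:
    _, chain, seq, icode = ref
    try:
        res = structure.residue(chain, seq, icode)
    except KeyError as exc:
        raise RestraintError(f"restraint residue {chain}/{seq}{icode} missing") from exc
    return res.heavy_coords()


def total_air_energy(receptor: Structure, ligand: Structure,
                     restraints: RestraintSet) -> float:
    """E_air: sum of flat-bottom energies over all (retained) AIRs; >= 0."""
    total = 0.0
    for air in restraints.airs:
        anchor_struct = receptor if air.anchor[0] == "receptor" else ligand
        anchor_xyz = _collect_heavy(anchor_struct, air.anchor)
        tgt_parts = []
        for t in air.targets:
            tgt_struct = receptor if t[0] == "receptor" else ligand
            tgt_parts.append(_collect_heavy(tgt_struct, t))
        d_eff = effective_distance(anchor_xyz, np.vstack(tgt_parts))
        total += air_energy(d_eff, air, restraints)
    return total


@dataclass(frozen=True)
class IndexedAIR:
    """An AIR resolved to heavy-atom indices of the two partners' coordinate
    arrays, for fast re-evaluation while the ligand pose changes."""

    anchor_on_receptor: bool
    anchor_idx: np.ndarray
    target_idx: np.ndarray  # indices into the partner's heavy-atom array
    upper_bound: float
    lower_bound: float


def _heavy_index_map(structure: Structure) -> dict[tuple, np.ndarray]:
    out, k = {}, 0
    for r in structure.residues:
        n = len(r.heavy_atoms)
        out[r.key] = np.arange(k, k + n)
        k += n
    return out


def index_airs(restraints: RestraintSet, receptor: Structure,
               ligand: Structure) -> list[IndexedAIR]:
    """Resolve every AIR to heavy-atom index arrays (receptor frame static,
    ligand frame mobile).  Raises RestraintError on missing residues."""
    rec_map, lig_map = _heavy_index_map(receptor), _heavy_index_map(ligand)

    def resolve(ref: ResidueRef) -> tuple[bool, np.ndarray]:
        side, chain, seq, icode = ref
        m = rec_map if side == "receptor" else lig_map
        try:
            return side == "receptor", m[(chain, seq, icode)]
        except KeyError as exc:
            raise RestraintError(f"restraint residue {chain}/{seq}{icode} missing") from exc

    out = []
    for air in restraints.airs:
        on_rec, anchor_idx = resolve(air.anchor)
        tgt = [resolve(t)[1] for t in air.targets]
        out.append(IndexedAIR(on_rec, anchor_idx, np.concatenate(tgt),
                              air.upper_bound, air.lower_bound))
    return out


def air_energy_from_coords(indexed: list[IndexedAIR], rec_xyz: np.ndarray,
                           lig_xyz: np.ndarray, params: RestraintSet) -> float:
    """E_air over pre-indexed AIRs given current heavy-atom coordinates."""
    k, sv = params.force_constant, params.switch_violation
    total = 0.0
    for ia in indexed:
        if ia.anchor_on_receptor:
            a, b = rec_xyz[ia.anchor_idx], lig_xyz[ia.target_idx]
        else:
            a, b = lig_xyz[ia.anchor_idx], rec_xyz[ia.target_idx]
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        d_eff = float(np.sum(d2 ** -3) ** (-1.0 / 6.0))
        if d_eff > ia.upper_bound:
            total += _flat_bottom(d_eff - ia.upper_bound, k, sv)
        elif d_eff < ia.lower_bound:
            total += _flat_bottom(ia.lower_bound - d_eff, k, sv)
    return total


def random_discard(restraints: RestraintSet, fraction: float = 0.5,
                   seed: int = 0) -> RestraintSet:
    """Return a copy retaining ceil((1-fraction)*n) AIRs, sampled without
    replacement; deterministic per seed.  Each docking model draws its own."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n = len(restraints.airs)
    keep = math.ceil((1.0 - fraction) * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return replace(restraints, airs=[restraints.airs[i] for i in idx])
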