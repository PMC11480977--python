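"""Intermolecular energy terms and the stage-weighted docking score.

The score combines five terms -- van der Waals (Lennard-Jones), Coulomb
electrostatics, an empirical surface-area desolvation energy, buried surface
area (BSA) and the ambiguous-restraint energy -- with weights that depend on
the docking stage:

    score = w_vdW*E_vdW + w_elec*E_elec + w_desolv*E_desolv
            + w_BSA*E_BSA + w_air*E_air          (lower is better)

Nonbonded parameters come from a compact built-in table (element-level
typing with carbonyl/hydroxyl oxygen split and an element fallback) that the
user may override; it stands in for a full force-field parameterization so
the toolkit is self-contained.  All terms operate on heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .restraints import RestraintSet, total_air_energy
from .structures import Structure

__all__ = [
    "NonbondedParams",
    "PartnerTerms",
    "EnergyReport",
    "ScoringWeights",
    "ParameterError",
    "resolve_params",
    "lennard_jones",
    "coulomb",
    "sasa",
    "bsa",
    "desolvation",
    "haddock_score",
    "score_pose",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


class ParameterError(KeyError):
    """Atom class missing from the nonbonded table with no fallback."""


# per-class entries: (lj_epsilon kcal/mol, lj_sigma A, partial charge e,
#                     atomic solvation parameter kcal/(mol*A^2))
_DEFAULT_TABLE = {
    "C":          (0.066, 3.50,  0.10,  0.0127),
    "C.aromatic": (0.070, 3.55,  0.00,  0.0127),
    "O.hydroxyl": (0.170, 3.12, -0.40, -0.0120),
    "O.carbonyl": (0.210, 2.96, -0.40, -0.0120),
    "N":          (0.170, 3.25, -0.35, -0.0090),
    "S":          (0.250, 3.55, -0.20,  0.0126),
    "P":          (0.200, 3.74,  0.40,  0.0000),
    "*":          (0.100, 3.40,  0.00,  0.0000),  # element fallback
}


@dataclass
class NonbondedParams:
    """Editable nonbonded parameter table with element-level fallback."""

    table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TABLE))
    relative_permittivity: float = 10.0
    cutoff: float = 8.5          # A, nonbonded cutoff
    switch_width: float = 1.5    # A, cubic switch over the last 1.5 A

    def __post_init__(self) -> None:
        for cls, (eps, sig, _q, _s) in self.table.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid LJ parameters for class {cls!r}")

    def lookup(self, atom_class: str):
        if atom_class in self.table:
            return self.table[atom_class]
        element = atom_class.split(".")[0]
        if element in self.table:
            return self.table[element]
        if "*" in self.table:
            return self.table["*"]
        raise ParameterError(f"no parameters for atom class {atom_class!r}")


def atom_class(residue_name: str, atom_name: str, element: str) -> str:
    """Simple atom typing: element with a carbonyl/hydroxyl oxygen split."""
    el = element.upper()
    if el == "O":
        # backbone carbonyl / carboxylate oxygens vs hydroxyl-like ones
        if atom_name in ("O", "OXT") or atom_name.startswith(("OD", "OE")):
            return "O.carbonyl"
        return "O.hydroxyl"
    return el


@dataclass
class PartnerTerms:
    """Per-heavy-atom parameter arrays for one docking partner.

    Resolved once per structure so pose scoring inside the minimizer loop is
    pure array arithmetic.
    """

    coords: np.ndarray   # (n, 3)
    epsilon: np.ndarray  # (n,)
    sigma: np.ndarray    # (n,)
    charge: np.ndarray   # (n,)
    solv: np.ndarray     # (n,)
    radii: np.ndarray    # (n,) vdW radii for SASA


def resolve_params(structure: Structure, params: NonbondedParams) -> PartnerTerms:
    eps, sig, q, sol, rad, xyz = [], [], [], [], [], []
    for res in structure.residues:
        for a in res.atoms:
            if not a.is_heavy:
                continue
            e, s, c, v = params.lookup(atom_class(res.name, a.name, a.element))
            eps.append(e); sig.append(s); q.append(c); sol.append(v)
            rad.append(a.vdw_radius)
            xyz.append(a.coords)
    return PartnerTerms(
        coords=np.array(xyz, dtype=float),
        epsilon=np.array(eps), sigma=np.array(sig),
        charge=np.array(q), solv=np.array(sol), radii=np.array(rad),
    )


def _switch(r: np.ndarray, cutoff: float, width: float) -> np.ndarray:
    """Cubic switching function: 1 below cutoff-width, 0 at cutoff."""
    x = np.clip((r - (cutoff - width)) / width, 0.0, 1.0)
    return 1.0 - x * x * (3.0 - 2.0 * x)


def lennard_jones(rec: PartnerTerms, lig: PartnerTerms,
                  params: NonbondedParams | None = None,
                  coords_rec: np.ndarray | None = None,
                  coords_lig: np.ndarray | None = None) -> float:
    """Intermolecular LJ energy, Lorentz-Berthelot combined, switched to zero
    at the cutoff.  E_vdW in kcal/mol."""
    params = params or NonbondedParams()
    xa = rec.coords if coords_rec is None else coords_rec
    xb = lig.coords if coords_lig is None else coords_lig
    r = cdist(xa, xb)
    mask = r < params.cutoff
    if not mask.any():
        return 0.0
    eps = np.sqrt(rec.epsilon[:, None] * lig.epsilon[None, :])[mask]
    sig = (0.5 * (rec.sigma[:, None] + lig.sigma[None, :]))[mask]
    rm = r[mask]
    sr6 = (sig / rm) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    return float(np.sum(e * _switch(rm, params.cutoff, params.switch_width)))


def coulomb(rec: PartnerTerms, lig: PartnerTerms,
            params: NonbondedParams | None = None,
            coords_rec: np.ndarray | None = None,
            coords_lig: np.ndarray | None = None) -> float:
    """Intermolecular Coulomb energy with constant relative permittivity,
    switched to zero at the cutoff.  E_elec in kcal/mol."""
    params = params or NonbondedParams()
    xa = rec.coords if coords_rec is None else coords_rec
    xb = lig.coords if coords_lig is None else coords_lig
    r = cdist(xa, xb)
    if np.any(r == 0.0):
        raise ValueError("coincident atoms (r = 0) in Coulomb term")
    mask = r < params.cutoff
    if not mask.any():
        return 0.0
    qq = (rec.charge[:, None] * lig.charge[None, :])[mask]
    rm = r[mask]
    e = COULOMB_CONSTANT * qq / (params.relative_permittivity * rm)
    return float(np.sum(e * _switch(rm, params.cutoff, params.switch_width)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by Shrake-Rupley sampling.

    Each atom's extended sphere (r_vdw + probe) is covered with ``n_points``
    quasi-uniform points; the accessible area is the fraction of points not
    buried inside any neighbour's extended sphere.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points >= 100 required for stable areas")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    ext = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def bsa(rec: PartnerTerms, lig: PartnerTerms,
        coords_rec: np.ndarray | None = None,
        coords_lig: np.ndarray | None = None,
        probe: float = 1.4, n_points: int = 960) -> float:
    """Buried surface area: SASA(receptor) + SASA(ligand) - SASA(complex)."""
    xa = rec.coords if coords_rec is None else coords_rec
    xb = lig.coords if coords_lig is None else coords_lig
    free = sasa(xa, rec.radii, probe, n_points).sum() + \
        sasa(xb, lig.radii, probe, n_points).sum()
    joint = sasa(np.vstack([xa, xb]), np.concatenate([rec.radii, lig.radii]),
                 probe, n_points).sum()
    return float(free - joint)


def desolvation(rec: PartnerTerms, lig: PartnerTerms,
                coords_rec: np.ndarray | None = None,
                coords_lig: np.ndarray | None = None,
                probe: float = 1.4, n_points: int = 960) -> float:
    """Empirical desolvation: sum over atoms of the atomic solvation
    parameter times the SASA lost upon complex formation (both partners)."""
    xa = rec.coords if coords_rec is None else coords_rec
    xb = lig.coords if coords_lig is None else coords_lig
    free_a = sasa(xa, rec.radii, probe, n_points)
    free_b = sasa(xb, lig.radii, probe, n_points)
    joint = sasa(np.vstack([xa, xb]), np.concatenate([rec.radii, lig.radii]),
                 probe, n_points)
    na = len(xa)
    buried_a = free_a - joint[:na]
    buried_b = free_b - joint[na:]
    return float(np.dot(rec.solv, buried_a) + np.dot(lig.solv, buried_b))


@dataclass
class EnergyReport:
    E_vdW: float = 0.0
    E_elec: float = 0.0
    E_desolv: float = 0.0
    E_BSA: float = 0.0
    E_air: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E_vdW", "E_elec", "E_desolv", "E_BSA", "E_air"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite energy term {name}")


@dataclass(frozen=True)
class ScoringWeights:
    """Stage-specific weight vector.  BSA carries a negative weight at the
    rigid stage so burial is rewarded (score is minimized)."""

    w_vdW: float
    w_elec: float
    w_desolv: float
    w_BSA: float
    w_air: float
    stage: str = "custom"

    @classmethod
    def rigid_default(cls) -> "ScoringWeights":
        return cls(0.01, 1.0, 1.0, -0.01, 0.01, stage="rigid-default")

    @classmethod
    def rigid_vdw(cls) -> "ScoringWeights":
        return cls(1.0, 1.0, 1.0, -0.01, 0.01, stage="rigid-vdW")

    @classmethod
    def flexref(cls) -> "ScoringWeights":
        return cls(1.0, 1.0, 1.0, 0.0, 0.1, stage="flexref")

    @classmethod
    def preset(cls, name: str) -> "ScoringWeights":
        try:
            return {"rigid-default": cls.rigid_default,
                    "rigid-vdW": cls.rigid_vdw,
                    "rigid-vdw": cls.rigid_vdw,
                    "flexref": cls.flexref}[name]()
        except KeyError:
            raise ValueError(f"unknown weight preset {name!r}") from None


def haddock_score(report: EnergyReport, weights: ScoringWeights) -> float:
    """Weighted linear combination of the energy terms; lower is better."""
    return (weights.w_vdW * report.E_vdW
            + weights.w_elec * report.E_elec
            + weights.w_desolv * report.E_desolv
            + weights.w_BSA * report.E_BSA
            + weights.w_air * report.E_air)


def score_pose(receptor: Structure, ligand: Structure,
               restraints: RestraintSet | None,
               weights: ScoringWeights,
               params: NonbondedParams | None = None,
               include_surface: bool = True,
               sasa_points: int = 240) -> tuple[EnergyReport, float]:
    """Full per-term evaluation of a posed complex and its weighted score."""
    params = params or NonbondedParams()
    rec = resolve_params(receptor, params)
    lig = resolve_params(ligand, params)
    e_vdw = lennard_jones(rec, lig, params)
    e_elec = coulomb(rec, lig, params)
    e_air = total_air_energy(receptor, ligand, restraints) if restraints else 0.0
    if include_surface:
        free_a = sasa(rec.coords, rec.radii, n_points=sasa_points)
        free_b = sasa(lig.coords, lig.radii, n_points=sasa_points)
        joint = sasa(np.vstack([rec.coords, lig.coords]),
                     np.concatenate([rec.radii, lig.radii]), n_points=sasa_points)
        na = len(rec.coords)
        e_bsa = max(float(free_a.sum() + free_b.sum() - joint.sum()), 0.0)
        e_dslv = float(np.dot(rec.solv, free_a - joint[:na])
                       + np.dot(lig.solv, free_b - joint[na:]))
    else:
        e_bsa = e_dslv = 0.0
    report = EnergyReport(e_vdw, e_elec, e_dslv, e_bsa, e_air)
    return report, haddock_score(report, weights)
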