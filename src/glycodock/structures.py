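"""Coordinate model for docking partners.

Structures are read from fixed-width PDB files (via gemmi) into a light
hierarchy of :class:`Atom` / :class:`Residue` / :class:`Structure` objects,
role-tagged as protein receptor or glycan ligand.  The module also detects
glycosidic linkages by geometry, classifies glycans by size/connectivity
(SL/SB/LL/LB) and selects interface residues by a heavy-atom distance
criterion (3.9 A by default).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "GlycanTopology",
    "SizeClass",
    "ResidueKind",
    "PDBFormatError",
    "EmptyStructureError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "build_glycan_topology",
    "classify_glycan",
    "select_interface",
]

# Catalogue of 3-letter monosaccharide residue names (common pyranose codes).
# User-extensible: pass extra names to read_pdb(..., extra_sugar_names=...).
MONOSACCHARIDE_NAMES = {
    "GLC", "BGC", "GAL", "GLA", "MAN", "BMA", "FUC", "FUL", "XYS", "XYP",
    "NAG", "NDG", "NGA", "A2G", "SIA", "SLB", "GCU", "BDP", "IDS", "IDR",
    "RIB", "RIP", "ARA", "ARB", "RAM", "RHA", "KDO", "NEU", "GCS", "PA1",
    "G6D", "ABE", "TYV", "MUR", "GDP_SUG", "GMH", "LGU", "MAV", "BEM",
}

AMINO_ACID_NAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "CYX", "HID", "HIE", "HIP",
}

PROTEIN_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Heavy-atom van der Waals radii (A) used for SASA-style computations.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70


class ResidueKind(enum.Enum):
    AMINO_ACID = "amino-acid"
    MONOSACCHARIDE = "monosaccharide"
    OTHER = "other"


class Role(enum.Enum):
    RECEPTOR = "receptor"
    LIGAND = "ligand"


class PDBFormatError(ValueError):
    """Unparseable or overflowing PDB content."""


class EmptyStructureError(ValueError):
    """A selection produced no atoms/residues."""


class TopologyError(ValueError):
    """Glycan linkage graph invalid (e.g. disconnected)."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float64, Angstrom
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_heavy(self) -> bool:
        return not self.is_hydrogen

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    name: str
    atoms: list[Atom]
    kind: ResidueKind = ResidueKind.OTHER
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.seq_id}: no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def backbone_atoms(self) -> list[Atom]:
        if self.kind is not ResidueKind.AMINO_ACID:
            return []
        return [a for a in self.atoms if a.name in PROTEIN_BACKBONE_NAMES and a.is_heavy]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.name} {self.seq_id}")


@dataclass
class Structure:
    """An ordered set of residues forming one docking partner.

    ``model_id`` distinguishes members of a multi-MODEL ensemble.
    """

    residues: list[Residue]
    role: Role = Role.RECEPTOR
    model_id: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_id, icode) within one model")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        """All-atom coordinate array, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def heavy_coords(self) -> np.ndarray:
        return self.coords()[self.heavy_mask()]

    def heavy_residue_index(self) -> np.ndarray:
        """Residue index of each heavy atom (parallel to heavy_coords)."""
        idx = []
        for i, r in enumerate(self.residues):
            idx.extend([i] * len(r.heavy_atoms))
        return np.array(idx, dtype=int)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def bounding_radius(self) -> float:
        xyz = self.heavy_coords()
        return float(np.linalg.norm(xyz - xyz.mean(axis=0), axis=1).max())

    def residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, seq_id, icode):
                return r
        raise KeyError(f"residue {chain_id}/{seq_id}{icode} not found")

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Deep copy with all-atom coordinates replaced (same atom order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        new_res = []
        k = 0
        for r in self.residues:
            new_atoms = []
            for a in r.atoms:
                new_atoms.append(replace(a, coords=xyz[k].copy()))
                k += 1
            new_res.append(replace(r, atoms=new_atoms))
        return Structure(new_res, role=self.role, model_id=self.model_id, name=self.name)

    def copy(self) -> "Structure":
        return self.with_coords(self.coords())


@dataclass(frozen=True)
class GlycanTopology:
    n_units: int
    linkage_edges: frozenset[tuple[int, int]]  # residue-index pairs, i < j
    is_linear: bool

    def degree(self, i: int) -> int:
        return sum(1 for e in self.linkage_edges if i in e)


@dataclass(frozen=True)
class SizeClass:
    label: str  # SL | SB | LL | LB

    def __post_init__(self) -> None:
        if self.label not in ("SL", "SB", "LL", "LB"):
            raise ValueError(f"unknown size class {self.label!r}")

    @property
    def is_short(self) -> bool:
        return self.label[0] == "S"

    @property
    def is_linear(self) -> bool:
        return self.label[1] == "L"


def _classify_residue_name(name: str, extra_sugar_names: set[str] | None = None) -> ResidueKind:
    name = name.strip().upper()
    if name in AMINO_ACID_NAMES:
        return ResidueKind.AMINO_ACID
    if name in MONOSACCHARIDE_NAMES or (extra_sugar_names and name in extra_sugar_names):
        return ResidueKind.MONOSACCHARIDE
    return ResidueKind.OTHER


def _convert_gemmi_model(model: gemmi.Model, role: Role, model_id: int,
                         extra_sugar_names: set[str] | None) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            # altloc policy: keep highest occupancy per atom name, tie -> first.
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = [
                Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name or "C",
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                )
                for at in best.values()
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                    kind=_classify_residue_name(res.name, extra_sugar_names),
                )
            )
    if not residues:
        raise EmptyStructureError(f"model {model_id}: no residues parsed")
    return Structure(residues, role=role, model_id=model_id)


def read_pdb(path, role: Role | str = Role.RECEPTOR,
             extra_sugar_names: set[str] | None = None) -> list[Structure]:
    """Read a PDB file into one Structure per MODEL block.

    Hydrogens are retained (flagged via :attr:`Atom.is_hydrogen`); altlocs are
    resolved to the highest-occupancy conformer.  Returns a list even for
    single-model files, so ensemble handling is uniform.
    """
    if isinstance(role, str):
        role = Role(role)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no MODEL blocks / ATOM records")
    out = []
    for i, model in enumerate(st, start=1):
        out.append(_convert_gemmi_model(model, role, i, extra_sugar_names))
    return out


_COORD_LIMIT = 9999.999  # PDB %8.3f field


def write_pdb(structures: Structure | list[Structure], path) -> None:
    """Write one or more Structures as a fixed-width (multi-)MODEL PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    if not structures:
        raise EmptyStructureError("nothing to write")
    for s in structures:
        xyz = s.coords()
        if np.abs(xyz).max() > _COORD_LIMIT:
            raise PDBFormatError("coordinate magnitude exceeds PDB field width")
    st = gemmi.Structure()
    st.name = structures[0].name or "glycodock"
    for s in structures:
        model = gemmi.Model(s.model_id)
        chains: dict[str, gemmi.Chain] = {}
        for r in s.residues:
            ch = chains.get(r.chain_id)
            if ch is None:
                ch = gemmi.Chain(r.chain_id)
                chains[r.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
            gres.het_flag = "A" if r.kind is ResidueKind.AMINO_ACID else "H"
            for a in r.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.coords)
                gat.occ = a.occupancy
                gres.add_atom(gat)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path), minimal=True)


def build_glycan_topology(glycan: Structure, bond_cutoff: float = 1.8) -> GlycanTopology:
    """Detect glycosidic linkages geometrically and derive the linkage graph.

    A linkage is recorded between two monosaccharide residues when a carbon of
    one lies within ``bond_cutoff`` of an oxygen of the other (the anomeric
    C1-Ox glycosidic contact); CONECT records are ignored as unreliable.
    """
    sugar_idx = [i for i, r in enumerate(glycan.residues)
                 if r.kind is ResidueKind.MONOSACCHARIDE]
    if not sugar_idx:
        raise EmptyStructureError("glycan contains no monosaccharide residues")
    g = nx.Graph()
    g.add_nodes_from(sugar_idx)
    carbons, oxygens = [], []
    for i in sugar_idx:
        for a in glycan.residues[i].atoms:
            el = a.element.upper()
            if el == "C":
                carbons.append((i, a.coords))
            elif el == "O":
                oxygens.append((i, a.coords))
    if carbons and oxygens:
        c_xyz = np.array([c for _, c in carbons])
        o_xyz = np.array([o for _, o in oxygens])
        pairs = cKDTree(c_xyz).query_ball_tree(cKDTree(o_xyz), r=bond_cutoff)
        for ci, ojs in enumerate(pairs):
            for oj in ojs:
                ri, rj = carbons[ci][0], oxygens[oj][0]
                if ri != rj:
                    g.add_edge(min(ri, rj), max(ri, rj))
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise TopologyError(f"glycan linkage graph disconnected: components {comps}")
    n = len(sugar_idx)
    degrees = [d for _, d in g.degree()]
    is_linear = (n == 1) or (g.number_of_edges() == n - 1 and max(degrees) <= 2)
    return GlycanTopology(
        n_units=n,
        linkage_edges=frozenset(tuple(sorted(e)) for e in g.edges()),
        is_linear=is_linear,
    )


def classify_glycan(topology: GlycanTopology) -> SizeClass:
    """SL/SB/LL/LB label: S = three or fewer units, L/B from linearity."""
    size = "S" if topology.n_units <= 3 else "L"
    shape = "L" if topology.is_linear else "B"
    return SizeClass(size + shape)


def select_interface(receptor: Structure, ligand: Structure,
                     cutoff: float = 3.9) -> tuple[list[Residue], list[Residue]]:
    """Interface residues: any heavy atom within ``cutoff`` of the partner.

    Symmetric in the two roles; returns (receptor residues, ligand residues).
    Emits a warning (not an error) when no contacts exist at the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rx, lx = receptor.heavy_coords(), ligand.heavy_coords()
    if rx.size == 0 or lx.size == 0:
        raise EmptyStructureError("empty structure in interface selection")
    ri, li = receptor.heavy_residue_index(), ligand.heavy_residue_index()
    pairs = cKDTree(rx).query_ball_tree(cKDTree(lx), r=cutoff)
    rec_sel, lig_sel = set(), set()
    for ai, hits in enumerate(pairs):
        if hits:
            rec_sel.add(ri[ai])
            lig_sel.update(li[h] for h in hits)
    if not rec_sel:
        warnings.warn(f"no interface contacts at cutoff {cutoff} A", stacklevel=2)
    return (
        [receptor.residues[i] for i in sorted(rec_sel)],
        [ligand.residues[i] for i in sorted(lig_sel)],
    )
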