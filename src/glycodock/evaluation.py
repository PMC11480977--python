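"""CAPRI-style model quality assessment for protein-glycan docking.

The central metric is the interface-ligand RMSD (IL-RMSD): the model is
superposed onto the reference complex using the backbone atoms of the
protein interface residues (interface defined on the reference at 3.9 A),
and the RMSD is then measured on the glycan heavy atoms without re-fitting.
This keeps the metric sensitive to the glycan placement, which a protein-
dominated interface RMSD would mask.  Quality tiers (inclusive bounds):

    high <= 1.0 A < medium <= 2.0 A < acceptable <= 3.0 A
    < near-acceptable <= 4.0 A < none

Success rates report, over a set of complexes, the fraction with at least
one model of a given tier or better among the top-N by score; the cluster-
based variant assigns each cluster the best tier among its top few members.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import Residue, Structure, select_interface

__all__ = [
    "Quality", "EvalRecord", "SuccessRateTable", "CorrespondenceError",
    "kabsch_superpose", "il_rmsd", "classify_quality", "success_rate",
    "cluster_success_rate", "plot_success_rates",
]


class CorrespondenceError(KeyError):
    """Model and reference atoms cannot be paired."""


class Quality(enum.IntEnum):
    """Ordered quality tiers; smaller is better."""

    HIGH = 1
    MEDIUM = 2
    ACCEPTABLE = 3
    NEAR_ACCEPTABLE = 4
    NONE = 5

    @property
    def label(self) -> str:
        return {1: "high", 2: "medium", 3: "acceptable",
                4: "near-acceptable", 5: "none"}[self.value]


TIERS = [Quality.HIGH, Quality.MEDIUM, Quality.ACCEPTABLE, Quality.NEAR_ACCEPTABLE]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation).

    Returns ``(R, t, rmsd)`` with ``y ~= R @ x + t`` mapping the mobile points
    onto the reference; the transform can then be applied to a whole model.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need two equal (n>=3, 3) coordinate arrays")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - rot @ xc
    fitted = (rot @ x.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, t, rmsd


# small synonym map for alternative glycan atom-naming dialects
DEFAULT_ATOM_SYNONYMS = {"O6A": "O6", "O1A": "O1", "C7": "C6"}


def _atom_map(structure: Structure, heavy_only: bool = True,
              synonyms: dict[str, str] | None = None) -> dict[tuple, np.ndarray]:
    syn = synonyms or {}
    out = {}
    for r in structure.residues:
        for a in r.atoms:
            if heavy_only and not a.is_heavy:
                continue
            name = syn.get(a.name, a.name)
            out[(r.chain_id, r.seq_id, r.icode, name)] = a.coords
    return out


def _paired_coords(model: Structure, reference: Structure,
                   residues: list[Residue], atom_filter,
                   synonyms: dict[str, str] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    mmap = _atom_map(model, synonyms=synonyms)
    mob, ref, missing = [], [], []
    for r in residues:
        for a in r.atoms:
            if not a.is_heavy or not atom_filter(r, a):
                continue
            key = (r.chain_id, r.seq_id, r.icode, a.name)
            m = mmap.get(key)
            if m is None:
                missing.append("/".join(map(str, key)))
            else:
                mob.append(m)
                ref.append(a.coords)
    if missing:
        raise CorrespondenceError(f"model lacks reference atoms: {missing}")
    return np.array(mob), np.array(ref)


def il_rmsd(model_receptor: Structure, model_ligand: Structure,
            ref_receptor: Structure, ref_ligand: Structure,
            interface_cutoff: float = 3.9,
            synonyms: dict[str, str] | None = None) -> float:
    """Interface-ligand RMSD of a model against the bound reference.

    Fit: backbone heavy atoms of the reference protein interface residues
    (interface at ``interface_cutoff`` on the reference complex).  Measure:
    glycan heavy atoms, after applying the fit transform to the whole model.
    """
    iface, _ = select_interface(ref_receptor, ref_ligand, cutoff=interface_cutoff)
    if len(iface) == 0:
        raise ValueError("reference complex has no interface at the cutoff")
    bb_names = {"N", "CA", "C", "O", "OXT"}
    fit_mob, fit_ref = _paired_coords(
        model_receptor, ref_receptor, iface,
        lambda r, a: a.name in bb_names, synonyms)
    rot, t, _ = kabsch_superpose(fit_mob, fit_ref)
    gly_mob, gly_ref = _paired_coords(
        model_ligand, ref_ligand, ref_ligand.residues,
        lambda r, a: True, synonyms)
    moved = (rot @ gly_mob.T).T + t
    return float(np.sqrt(np.mean(np.sum((moved - gly_ref) ** 2, axis=1))))


def classify_quality(il: float) -> Quality:
    """Quality tier from IL-RMSD; boundaries are inclusive (<=)."""
    if il < 0:
        raise ValueError("IL-RMSD must be non-negative")
    if il <= 1.0:
        return Quality.HIGH
    if il <= 2.0:
        return Quality.MEDIUM
    if il <= 3.0:
        return Quality.ACCEPTABLE
    if il <= 4.0:
        return Quality.NEAR_ACCEPTABLE
    return Quality.NONE


@dataclass(frozen=True)
class EvalRecord:
    model_id: int
    il_rmsd: float
    quality: Quality
    rank_by_score: int

    @classmethod
    def from_rmsd(cls, model_id: int, il: float, rank: int) -> "EvalRecord":
        return cls(model_id, il, classify_quality(il), rank)


@dataclass
class SuccessRateTable:
    """Success-rate fractions indexed by top-N, one column per quality tier.

    A complex counts for a tier if at least one of its top-N models (or
    top-N clusters, for the cluster-based variant) reaches that tier or
    better; fractions are over complexes and cumulative across tiers.
    """

    frame: pd.DataFrame  # index: top-N; columns: tier labels

    def __post_init__(self) -> None:
        v = self.frame.to_numpy()
        if ((v < -1e-9) | (v > 1 + 1e-9)).any():
            raise ValueError("success-rate fractions outside [0, 1]")

    def value(self, top_n: int, tier: Quality) -> float:
        return float(self.frame.loc[top_n, tier.label])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="top_n")


def _sr_frame(per_complex_best: list[dict[int, int]],
              tops: tuple[int, ...]) -> pd.DataFrame:
    # per_complex_best: for each complex, map top-N -> best tier value in top N
    data = {}
    for tier in TIERS:
        col = []
        for n in tops:
            hits = sum(1 for best in per_complex_best
                       if best.get(n, Quality.NONE) <= tier)
            col.append(hits / len(per_complex_best))
        data[tier.label] = col
    return pd.DataFrame(data, index=list(tops))


def success_rate(records_per_complex: list[list[EvalRecord]],
                 tops: tuple[int, ...] = (1, 5, 10, 50, 100, 200)
                 ) -> SuccessRateTable:
    """Single-model success rates over a set of complexes."""
    if not records_per_complex:
        raise ValueError("no complexes to evaluate")
    per_complex = []
    for records in records_per_complex:
        ranked = sorted(records, key=lambda r: r.rank_by_score)
        best = {}
        for n in tops:
            vals = [r.quality for r in ranked if r.rank_by_score <= n]
            best[n] = min(vals) if vals else Quality.NONE
        per_complex.append(best)
    return SuccessRateTable(_sr_frame(per_complex, tops))


def cluster_success_rate(clusters_per_complex: list[list[list[EvalRecord]]],
                         top_members: int = 4,
                         tops: tuple[int, ...] = tuple(range(1, 11))
                         ) -> SuccessRateTable:
    """Cluster-based success rates.

    ``clusters_per_complex``: per complex, a rank-ordered list of clusters,
    each a score-ordered list of its members' EvalRecords.  A cluster's tier
    is the best tier among its ``top_members`` first members (4 after
    refinement, 5 at the rigid stage per the clustering convention).
    """
    if not clusters_per_complex:
        raise ValueError("no complexes to evaluate")
    per_complex = []
    for clusters in clusters_per_complex:
        tiers = [min((r.quality for r in c[:top_members]), default=Quality.NONE)
                 for c in clusters]
        best = {}
        for n in tops:
            vals = tiers[:n]
            best[n] = min(vals) if vals else Quality.NONE
        per_complex.append(best)
    return SuccessRateTable(_sr_frame(per_complex, tops))


def plot_success_rates(tables: dict[str, SuccessRateTable], tier: Quality,
                       path=None):
    """Grouped bar chart of success rates per top-N for one quality tier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(tables)
    tops = list(next(iter(tables.values())).frame.index)
    width = 0.8 / len(names)
    for i, name in enumerate(names):
        vals = [tables[name].value(n, tier) * 100 for n in tops]
        ax.bar(np.arange(len(tops)) + i * width, vals, width, label=name)
    ax.set_xticks(np.arange(len(tops)) + 0.4 - width / 2)
    ax.set_xticklabels([f"T{n}" for n in tops])
    ax.set_ylabel(f"success rate, {tier.label} (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
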