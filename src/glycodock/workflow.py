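"""Composed docking protocols: bound (6 stages) and unbound (12 stages).

Bound protocol: topology -> rigid-body docking -> model evaluation -> RMSD
matrix -> clustering (2.5 A average-linkage cut, min size 4) -> cluster
evaluation.  No flexible refinement: the partners are already bound forms.

Unbound protocol: topology -> rigid-body docking (1000 models, or 200 per
conformer for an ensemble) -> evaluation -> RMSD matrix -> clustering into
50 flat clusters (150 with an ensemble) -> selection of the top 5 models of
each cluster (or, in classical mode, the top 200 models overall) -> flexible
refinement -> evaluation -> RMSD matrix -> clustering at 2.5 A -> cluster
evaluation.  Every stage's tables are persisted; a run is exactly
reproducible from its echoed configuration and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering as clu
from .energetics import NonbondedParams, ScoringWeights
from .evaluation import EvalRecord, cluster_success_rate, il_rmsd, success_rate
from .fixtures import ToyComplex
from .refinement import flex_refine
from .restraints import Scenario, build_airs
from .rigid_docking import (DockingModel, SamplingConfig, generate_models,
                            models_table)
from .structures import (Structure, build_glycan_topology, classify_glycan,
                         write_pdb)

__all__ = ["RunConfig", "RunReport", "run_bound", "run_unbound"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scenario: str = "ti-aa"                 # ti-aa | tip-ap
    weights_preset: str = "rigid-vdW"       # rigid-default | rigid-vdW
    interface_cutoff: float = 3.9
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    cluster_distance: float = 2.5
    min_cluster_size: int = 4
    rigid_n_clusters: int = 50              # 150 when docking an ensemble
    rigid_n_clusters_ensemble: int = 150
    models_per_cluster: int = 5
    classical_mode: bool = False            # top-200 selection instead
    classical_top: int = 200
    refine_steps_per_stage: int = 500
    seed: int = 0
    outdir: str | None = None

    def echo(self) -> dict:
        d = asdict(self)
        d["sampling"] = asdict(self.sampling)
        return d


@dataclass
class RunReport:
    config: RunConfig
    models: list[DockingModel]
    records: list[EvalRecord]
    cluster_set: clu.ClusterSet | None = None
    refined: list[DockingModel] | None = None
    refined_records: list[EvalRecord] | None = None
    refined_clusters: clu.ClusterSet | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def best_il_rmsd(self, top_n: int | None = None) -> float:
        recs = self.refined_records or self.records
        pool = [r for r in recs if top_n is None or r.rank_by_score <= top_n]
        return min(r.il_rmsd for r in pool)


def _evaluate(models: list[DockingModel], receptor: Structure,
              reference: tuple[Structure, Structure],
              cutoff: float) -> list[EvalRecord]:
    ref_r, ref_l = reference
    records = []
    for rank, m in enumerate(models, start=1):
        rec = m.receptor if m.receptor is not None else receptor
        il = il_rmsd(rec, m.ligand, ref_r, ref_l, interface_cutoff=cutoff)
        records.append(EvalRecord.from_rmsd(m.model_id, il, rank))
    return records


def _records_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model_id": r.model_id, "rank_by_score": r.rank_by_score,
        "il_rmsd": r.il_rmsd, "quality": r.quality.label} for r in records])


def _persist(report: RunReport, outdir: str | None) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(report.config.echo(), fh, sort_keys=True)
    for name, frame in report.tables.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.6f")
    if report.models:
        write_pdb([m.ligand for m in report.models[:50]],
                  out / "top_ligand_poses.pdb")


def _cluster_records(cluster_set: clu.ClusterSet,
                     records: list[EvalRecord]) -> list[list[EvalRecord]]:
    by_id = {r.model_id: r for r in records}
    return [[by_id[m] for m in c.members] for c in cluster_set.clusters]


def run_bound(receptor: Structure, glycan: Structure,
              reference: tuple[Structure, Structure] | None,
              config: RunConfig,
              params: NonbondedParams | None = None) -> RunReport:
    """Six-stage bound-docking protocol on one complex."""
    t0 = time.time()
    reference = reference or (receptor, glycan)
    topology = build_glycan_topology(glycan)
    log.info("glycan: %d units, class %s", topology.n_units,
             classify_glycan(topology).label)
    restraints = build_airs(receptor, glycan, config.scenario,
                            interface_cutoff=config.interface_cutoff,
                            reference=reference)
    weights = ScoringWeights.preset(config.weights_preset)
    models = generate_models(receptor, glycan, restraints, config.sampling,
                             weights, params)
    records = _evaluate(models, receptor, reference, config.interface_cutoff)
    matrix = clu.rmsd_matrix(models, receptor, reference,
                             mode=config.scenario,
                             interface_cutoff=config.interface_cutoff)
    scores = {m.model_id: m.score for m in models}
    cluster_set = clu.cluster_hier(matrix,
                                   scores,
                                   cut=("distance", config.cluster_distance),
                                   min_size=config.min_cluster_size)
    cluster_set = clu.rank_clusters(cluster_set, scores)
    report = RunReport(config, models, records, cluster_set=cluster_set)
    report.tables["scores_rigid"] = models_table(models)
    report.tables["eval_rigid"] = _records_frame(records)
    report.tables["clusters_rigid"] = clu.cluster_report(cluster_set)
    sr = success_rate([records])
    csr = cluster_success_rate([_cluster_records(cluster_set, records)],
                               top_members=5)
    report.tables["sr_single"] = sr.frame.reset_index(names="top_n")
    report.tables["sr_cluster"] = csr.frame.reset_index(names="top_n")
    _persist(report, config.outdir)
    log.info("bound run finished in %.1f s", time.time() - t0)
    return report


def run_unbound(receptor: Structure,
                glycan: Structure | list[Structure],
                reference: tuple[Structure, Structure],
                config: RunConfig,
                params: NonbondedParams | None = None) -> RunReport:
    """Twelve-stage unbound protocol with cluster-based (default) or
    classical top-N selection feeding the flexible refinement."""
    t0 = time.time()
    is_ensemble = isinstance(glycan, list)
    first = glycan[0] if is_ensemble else glycan
    build_glycan_topology(first)  # validates connectivity
    restraints = build_airs(receptor, first, config.scenario,
                            interface_cutoff=config.interface_cutoff,
                            reference=reference)
    weights = ScoringWeights.preset(config.weights_preset)
    models = generate_models(receptor, glycan, restraints, config.sampling,
                             weights, params)
    records = _evaluate(models, receptor, reference, config.interface_cutoff)
    matrix = clu.rmsd_matrix(models, receptor, reference,
                             mode=config.scenario,
                             interface_cutoff=config.interface_cutoff)
    scores = {m.model_id: m.score for m in models}
    n_clusters = (config.rigid_n_clusters_ensemble if is_ensemble
                  else config.rigid_n_clusters)
    n_clusters = min(n_clusters, len(models))
    rigid_clusters = clu.rank_clusters(
        clu.cluster_hier(matrix, scores, cut=("n_clusters", n_clusters),
                         min_size=config.min_cluster_size), scores)
    if config.classical_mode:
        selected_ids = [m.model_id for m in models[:config.classical_top]]
    else:
        selected_ids = clu.select_top_clusters(rigid_clusters,
                                               config.models_per_cluster)
    by_id = {m.model_id: m for m in models}
    refined = []
    for mid in selected_ids:
        refined.append(flex_refine(receptor, by_id[mid], restraints,
                                   params=params,
                                   steps_per_stage=config.refine_steps_per_stage,
                                   sasa_points=config.sampling.sasa_points))
    refined.sort(key=lambda m: (m.score, m.model_id))
    refined_records = _evaluate(refined, receptor, reference,
                                config.interface_cutoff)
    report = RunReport(config, models, records, cluster_set=rigid_clusters,
                       refined=refined, refined_records=refined_records)
    report.tables["scores_rigid"] = models_table(models)
    report.tables["eval_rigid"] = _records_frame(records)
    report.tables["clusters_rigid"] = clu.cluster_report(rigid_clusters)
    report.tables["scores_flexref"] = models_table(refined)
    report.tables["eval_flexref"] = _records_frame(refined_records)
    report.tables["sr_single_rigid"] = success_rate(
        [records]).frame.reset_index(names="top_n")
    report.tables["sr_cluster_rigid"] = cluster_success_rate(
        [_cluster_records(rigid_clusters, records)],
        top_members=config.models_per_cluster).frame.reset_index(names="top_n")
    if len(refined) >= 2:
        ref_matrix = clu.rmsd_matrix(refined, receptor, reference,
                                     mode=config.scenario,
                                     interface_cutoff=config.interface_cutoff)
        ref_scores = {m.model_id: m.score for m in refined}
        refined_clusters = clu.rank_clusters(
            clu.cluster_hier(ref_matrix, ref_scores,
                             cut=("distance", config.cluster_distance),
                             min_size=config.min_cluster_size), ref_scores)
        report.refined_clusters = refined_clusters
        report.tables["clusters_flexref"] = clu.cluster_report(refined_clusters)
        report.tables["sr_cluster_flexref"] = cluster_success_rate(
            [_cluster_records(refined_clusters, refined_records)],
            top_members=4).frame.reset_index(names="top_n")
    report.tables["sr_single_flexref"] = success_rate(
        [refined_records]).frame.reset_index(names="top_n")
    _persist(report, config.outdir)
    log.info("unbound run finished in %.1f s", time.time() - t0)
    return report
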