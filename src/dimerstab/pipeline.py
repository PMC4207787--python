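"""End-to-end orchestration of the stabilizer-screening protocol.

Stage order mirrors the screening funnel: synthesize (or load) an
ensemble, validate its dynamics, cluster binding-site conformations and
pick medoids, triage pockets near the target residue by druggability,
filter the compound library, intersect the two engines' top-N ranks per
conformation, rescore the pooled candidates by rigid/relaxed binding
energy, and keep the best candidates below the energy threshold.  Every
stage logs one structured line and contributes counts to a machine-
readable report whose funnel is monotone nonincreasing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as clu
from . import consensus as cons
from . import dynamics as dyn
from . import energy as ene
from . import pockets as poc
from . import synth
from .chem import FilterResult, MoleculeRecord, ppi_druglike_filter
from .structio import select_atoms

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, fully enumerated configuration; unknown keys are errors."""

    seed: int = 1
    # stage toggles
    run_synth: bool = True
    run_dynamics: bool = True
    run_cluster: bool = True
    run_pockets: bool = True
    run_filter: bool = True
    run_consensus: bool = True
    run_energy: bool = True
    # generator conditions
    n_residues: int = 60
    k_states: int = 8
    n_snapshots: int = 1500
    state_amplitude: float = 3.0
    thermal_sigma: float = 0.15
    library_size: int = 5000
    n_binders: int = 10
    violation_fraction: float = 0.25
    score_noise: float = 0.5
    ddg_noise: float = 2.0
    n_energy_snapshots: int = 60
    # thresholds
    cut_height: float = 1.3  # A, dendrogram cut
    population_radius: float = 1.5  # A
    druggability_floor: float = 0.80
    pocket_spacing: float = 1.0  # A
    burial_threshold: int = 16
    pocket_near_dist: float = 10.0  # A to the target residue
    n_conformations: int = 3  # receptor conformations carried to docking
    top_n: int = 2000
    ddg_window: int = 20
    ddg_threshold: float = -20.0
    final_count: int = 51
    out_dir: str = ""

    _BOOL_KEYS = frozenset({
        "run_synth", "run_dynamics", "run_cluster", "run_pockets",
        "run_filter", "run_consensus", "run_energy"})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config; '#' starts a comment.
        Unknown keys fail fast."""
        known = {f.name: f.type for f in dataclasses.fields(cls)
                 if not f.name.startswith("_")}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in cls._BOOL_KEYS:
                if raw.lower() not in ("true", "false"):
                    raise ValueError(f"{path}:{lineno}: {key} must be boolean")
                kwargs[key] = raw.lower() == "true"
            elif key == "out_dir":
                kwargs[key] = raw
            else:
                default = getattr(cls(), key)
                kwargs[key] = type(default)(float(raw)) \
                    if isinstance(default, int) and not isinstance(default, bool) \
                    else (float(raw) if isinstance(default, float) else raw)
        return cls(**kwargs)

    def to_synth_spec(self) -> synth.SynthSpec:
        return synth.SynthSpec(
            seed=self.seed, n_residues=self.n_residues,
            k_states=self.k_states, state_amplitude=self.state_amplitude,
            thermal_sigma=self.thermal_sigma, n_snapshots=self.n_snapshots,
            library_size=self.library_size, n_binders=self.n_binders,
            violation_fraction=self.violation_fraction,
            score_noise=self.score_noise, ddg_noise=self.ddg_noise,
            n_energy_snapshots=self.n_energy_snapshots)


@dataclass
class RunReport:
    """Machine-readable outcome of one pipeline run."""

    seed: int
    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    timestamp: float = 0.0

    def to_dict(self, with_timestamp: bool = True) -> dict:
        d = {"seed": self.seed, "parameters": self.parameters,
             "counts": self.counts, "metrics": self.metrics,
             "selected": self.selected}
        if with_timestamp:
            d["timestamp"] = self.timestamp
        return d

    def to_json(self, with_timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(with_timestamp), indent=2,
                          sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in funnel order and return the report."""
    report = RunReport(seed=config.seed, timestamp=time.time())
    report.parameters = {
        k: v for k, v in dataclasses.asdict(config).items()}
    spec = config.to_synth_spec()
    outdir = Path(config.out_dir) if config.out_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    ensemble = state_labels = references = None
    structure = None
    if config.run_synth:
        stage = "synth"
        try:
            structure = synth.make_toy_dimer(spec)
            ensemble, state_labels, references = synth.make_ensemble(
                structure, spec)
            report.counts["frames"] = ensemble.n_frames
            report.counts["atoms"] = len(structure)
            logger.info("synth: %d frames x %d atoms, k=%d planted states",
                        ensemble.n_frames, len(structure), spec.k_states)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_dynamics and ensemble is not None:
        stage = "dynamics"
        try:
            ca = select_atoms(structure, "atoms=ca")
            profile = dyn.rmsf(ensemble, sel=ca)
            report.metrics["mean_rmsf_ca"] = float(np.mean(profile.rmsf))
            report.metrics["mean_pseudo_bfactor"] = float(
                np.mean(profile.pseudo_bfactor))
            logger.info("dynamics: mean CA RMSF %.3f A",
                        report.metrics["mean_rmsf_ca"])
        except Exception as exc:
            raise StageError(stage, exc) from exc

    clustering = matrix = None
    medoid_frames: list[int] = []
    if config.run_cluster and ensemble is not None:
        stage = "cluster"
        try:
            site = synth.binding_site_selection(
                structure, spec.interface_cutoff)
            matrix = clu.pairwise_rmsd_matrix(ensemble, site)
            clustering = clu.ward_hac(matrix, cut_height=config.cut_height)
            report.counts["clusters"] = clustering.n_clusters
            sizes = np.bincount(clustering.labels)
            order = np.argsort(-sizes, kind="stable")
            medoid_frames = [int(clustering.medoids[c]) for c in order]
            top_medoid = medoid_frames[0]
            report.metrics["top_medoid_frame"] = top_medoid
            report.metrics["top_medoid_population"] = clu.population_density(
                matrix, top_medoid, config.population_radius)
            logger.info("cluster: %d clusters at cut %.2f A; top medoid "
                        "frame %d (population %d within %.1f A)",
                        clustering.n_clusters, config.cut_height, top_medoid,
                        report.metrics["top_medoid_population"],
                        config.population_radius)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_pockets and ensemble is not None and medoid_frames:
        stage = "pockets"
        try:
            medoid_structure = ensemble.frame(medoid_frames[0])
            pockets = poc.analyze_pockets(
                medoid_structure, spacing=config.pocket_spacing,
                burial_threshold=config.burial_threshold)
            report.counts["pockets"] = len(pockets)
            # target: central interface residue of chain C
            site = synth.binding_site_selection(
                structure, spec.interface_cutoff)
            c_res = sorted({
                int(r) for c, r in zip(
                    structure.chain_ids[site.indices],
                    structure.res_seqs[site.indices]) if c == "C"})
            target_res = c_res[len(c_res) // 2]
            report.parameters["target_residue"] = f"C:{target_res}"
            near = poc.pockets_near_residue(
                pockets, medoid_structure, "C", target_res,
                config.pocket_near_dist,
                min_score=config.druggability_floor)
            report.counts["druggable_pockets_near_target"] = len(near)
            if pockets:
                report.metrics["best_pocket_volume"] = pockets[0].volume
                report.metrics["best_pocket_druggability"] = max(
                    p.druggability for p in pockets)
            logger.info("pockets: %d detected, %d druggable (score >= %.2f) "
                        "within %.0f A of %s", len(pockets), len(near),
                        config.druggability_floor, config.pocket_near_dist,
                        report.parameters["target_residue"])
        except Exception as exc:
            raise StageError(stage, exc) from exc

    library = None
    filtered_ids: list[str] = []
    if config.run_filter:
        stage = "filter"
        try:
            library = synth.make_library(spec)
            results: list[FilterResult] = []
            for row in library.itertuples(index=False):
                rec = MoleculeRecord(
                    id=row.id, smiles=row.smiles, mw=row.mw, logp=row.logp,
                    tpsa=row.tpsa, hbd=row.hbd, hba=row.hba, rotb=row.rotb)
                results.append(ppi_druglike_filter(rec))
            passed = np.array([r.passed for r in results])
            filtered_ids = library.loc[passed, "id"].tolist()
            report.counts["library"] = len(library)
            report.counts["filtered"] = len(filtered_ids)
            truth = library["true_pass"].to_numpy()
            report.metrics["filter_agreement_with_planted"] = float(
                np.mean(passed == truth))
            logger.info("filter: %d/%d compounds pass the PPI-adapted "
                        "windows", len(filtered_ids), len(library))
        except Exception as exc:
            raise StageError(stage, exc) from exc

    pooled = None
    binders: list[str] = []
    if config.run_consensus and filtered_ids:
        stage = "consensus"
        try:
            n_conf = max(1, min(config.n_conformations,
                                len(medoid_frames) or config.n_conformations))
            if medoid_frames:
                conf_labels = tuple(
                    f"conf_{f}" for f in medoid_frames[:n_conf])
            else:
                conf_labels = tuple(f"conf_{i}" for i in range(n_conf))
            spec_scores = dataclasses.replace(
                spec, conformations=conf_labels)
            tables, binders = synth.make_score_tables(
                spec_scores, filtered_ids)
            per_conf = []
            flat_tables = []
            for conf, (ta, tb) in tables.items():
                per_conf.append(cons.consensus_for_conformation(
                    ta, tb, n=config.top_n))
                flat_tables.extend([ta, tb])
            pooled = cons.pool_conformations(per_conf, flat_tables)
            report.counts["consensus_per_conformation"] = {
                c: n for c, n in sorted(
                    pooled.per_conformation_counts.items())}
            report.counts["consensus_sum"] = pooled.count_sum
            report.counts["consensus_union"] = len(pooled.union)
            logger.info("consensus: union %d (sum %d) over %d conformations "
                        "at top-%d", len(pooled.union), pooled.count_sum,
                        len(per_conf), config.top_n)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_energy and pooled is not None and library is not None:
        stage = "energy"
        try:
            id_index = {cid: i for i, cid in enumerate(library["id"])}
            binder_set = set(binders)
            results = []
            for cid in sorted(pooled.union):
                ddg_true = (spec.ddg_true_binder if cid in binder_set
                            else spec.ddg_true_nonbinder)
                trajs = synth.make_energy_traj(spec, id_index[cid], ddg_true)
                rigid = ene.ddg_rigid(
                    trajs[("complex", "extracted")],
                    trajs[("receptor", "extracted")],
                    trajs[("ligand", "extracted")],
                    window=config.ddg_window)
                relaxed = ene.ddg_relaxed(
                    trajs[("complex", "extracted")],
                    trajs[("receptor", "independent")],
                    trajs[("ligand", "independent")],
                    window=config.ddg_window)
                results.append(ene.BindingEnergyResult(
                    compound_id=cid, ddg_rigid=rigid, ddg_relaxed=relaxed,
                    n_snapshots_averaged=config.ddg_window))
            selected = ene.select_candidates(
                results, threshold=config.ddg_threshold,
                max_candidates=config.final_count)
            report.counts["ddg_computed"] = len(results)
            report.counts["selected"] = len(selected)
            report.selected = [r.compound_id for r in selected]
            sel_set = set(report.selected)
            report.metrics["planted_binders"] = len(binders)
            report.metrics["planted_binders_recovered"] = len(
                binder_set & sel_set)
            if selected:
                report.metrics["best_ddg"] = float(
                    min(r.best for r in selected))
                binder_rigid = [r.ddg_rigid for r in results
                                if r.compound_id in binder_set]
                if binder_rigid:
                    report.metrics["mean_ddg_rigid_binders"] = float(
                        np.mean(binder_rigid))
            logger.info("energy: %d candidates rescored, %d selected at "
                        "threshold %.0f kcal/mol (%d/%d planted binders)",
                        len(results), len(selected), config.ddg_threshold,
                        report.metrics.get("planted_binders_recovered", 0),
                        len(binders))
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # funnel consistency check
    funnel = [report.counts.get(k) for k in
              ("library", "filtered", "consensus_union", "selected")]
    present = [v for v in funnel if v is not None]
    if any(a < b for a, b in zip(present, present[1:])):
        raise RuntimeError(f"funnel counts are not monotone: {funnel}")

    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report
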