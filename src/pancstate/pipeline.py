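"""End-to-end workflow orchestration with per-stage provenance.

Two named workflows mirror the two analysis arms.  The exocrine workflow
runs QC -> exocrine cluster selection -> axis scoring/subtype assignment
-> activity inference + residualization -> embedding tuning -> hurdle
models (equal weights) -> module associations (global + stratified) ->
trajectory lineages -> rank export.  The tumor workflow runs QC (tumor
preset) -> signature scoring / family classification -> activity ->
hurdle models (2:1 detection:continuous) -> rank export.

Every stage writes TSV outputs plus a JSON provenance record (parameters,
seed, SHA-256 of its inputs).  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .activity import first_pc, infer_activity, residualize_activity
from .datamodel import AnnotatedMatrix, GeneSetCollection
from .embedding import compute_pc_spaces, tune_combined_embedding
from .hurdle import EXOCRINE_COVARIATES, TUMOR_COVARIATES, HurdleModel
from .modules_assoc import ModuleAssociationModel
from .qc import QCThresholds, apply_qc_filter, select_exocrine
from .scoring import DEFAULT_AXIS_TO_LABEL, assign_axis_subtype, score_axes
from .simulate import (
    ExocrineSimConfig,
    generate_exocrine_dataset,
    generate_regulon,
    generate_tumor_dataset,
)
from .trajectory import (
    activity_composition_profile,
    compute_lineage_metrics,
    infer_pseudotime,
    select_representative_lineages,
)
from .tumor import score_signatures

log = logging.getLogger("pancstate.pipeline")

FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    workflow: str = "exocrine"  # or "tumor"
    outdir: str = "pancstate_run"
    seed: int = 0
    # synthetic-input parameters (used when no input paths are given)
    n_cells: int = 2000
    n_genes: int = 1500
    # optional pre-existing inputs
    matrix_path: str | None = None
    genes_path: str | None = None
    barcodes_path: str | None = None
    meta_path: str | None = None
    regulon_path: str | None = None
    panels_path: str | None = None
    modules_path: str | None = None
    signatures_path: str | None = None
    # stage parameters
    tf_name: str = "TF1"
    hurdle_max_genes: int = 200
    min_pos: int = 25
    n_hvg: int = 3000
    n_pcs: int = 30
    n_lineages: int = 3
    clip: float = 10.0

    def validate(self) -> None:
        if self.workflow not in ("exocrine", "tumor"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        for attr in ("matrix_path", "genes_path", "barcodes_path", "meta_path",
                     "regulon_path", "panels_path", "modules_path", "signatures_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {attr} refers to missing file {p}")


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _Runner:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def provenance(self, stage: str, params: dict, inputs: list, outputs: list) -> None:
        def rel(p) -> str:
            p = Path(p)
            try:
                return str(p.relative_to(self.outdir))
            except ValueError:
                return p.name

        record = {
            "stage": stage,
            "seed": self.cfg.seed,
            "params": params,
            "input_hashes": {rel(p): _sha256(p) for p in inputs},
            "outputs": [rel(p) for p in outputs],
        }
        path = self.outdir / f"provenance_{stage}.json"
        path.write_text(json.dumps(record, sort_keys=True, indent=2) + "\n")

    def write_frame(self, frame: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.outdir / name
        frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
        return path


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured workflow; returns the output directory."""
    cfg.validate()
    runner = _Runner(cfg)
    if cfg.workflow == "exocrine":
        _run_exocrine(runner)
    else:
        _run_tumor(runner)
    return runner.outdir


def _simulate_stage_exocrine(runner: _Runner):
    cfg = runner.cfg
    sim_cfg = ExocrineSimConfig(
        n_cells=cfg.n_cells, n_genes=cfg.n_genes, tf_name=cfg.tf_name, seed=cfg.seed
    )
    m, truth, regulon, panels = generate_exocrine_dataset(sim_cfg)
    out = runner.outdir
    psio.write_counts_mtx(m, out / "matrix.mtx", out / "genes.tsv", out / "barcodes.tsv")
    meta_path = runner.write_frame(m.cell_meta, "cell_meta.tsv")
    psio.write_regulon(regulon, out / "regulon.tsv")
    psio.write_gene_sets(panels, out / "panels.gmt")
    modules = GeneSetCollection(sets=truth.module_sets, kind="gene_module")
    psio.write_gene_sets(modules, out / "modules.gmt")
    truth_frame = pd.DataFrame(
        {
            "activity_true": truth.activity_true,
            "subtype_true": truth.subtype_true,
            "pseudotime_true": truth.pseudotime_true,
        }
    )
    runner.write_frame(truth_frame, "truth.tsv")
    runner.provenance(
        "simulate", {"n_cells": cfg.n_cells, "n_genes": cfg.n_genes}, [],
        [out / "matrix.mtx", meta_path],
    )
    return m, truth, regulon, panels, modules


def _load_inputs(runner: _Runner):
    cfg = runner.cfg
    m = psio.read_counts_mtx(cfg.matrix_path, cfg.genes_path, cfg.barcodes_path)
    meta = psio.read_cell_meta(cfg.meta_path)
    m = psio.attach_cell_meta(m, meta)
    from .datamodel import log_normalize

    m = log_normalize(m)
    regulon = psio.read_regulon(cfg.regulon_path) if cfg.regulon_path else None
    panels = psio.read_gene_sets(cfg.panels_path, "axis_panel") if cfg.panels_path else None
    modules = psio.read_gene_sets(cfg.modules_path, "gene_module") if cfg.modules_path else None
    return m, None, regulon, panels, modules


def _run_exocrine(runner: _Runner) -> None:
    cfg = runner.cfg
    stage = "simulate"
    try:
        if cfg.matrix_path is None:
            m, truth, regulon, panels, modules = _simulate_stage_exocrine(runner)
        else:
            m, truth, regulon, panels, modules = _load_inputs(runner)
            if regulon is None or panels is None:
                raise ValueError("exocrine workflow requires regulon and panels inputs")

        stage = "qc"
        kept, report = apply_qc_filter(m, QCThresholds.exocrine())
        runner.write_frame(report.to_frame(), "qc_report.tsv")
        runner.provenance(stage, {"preset": "exocrine"}, [], [runner.outdir / "qc_report.tsv"])
        log.info("qc: kept %d / %d cells", kept.n_cells, m.n_cells)

        stage = "select_exocrine"
        acinar_panel = panels["acinar"]
        ductal_panel = panels["ductal_core_1"]
        kept = select_exocrine(kept, acinar_panel, ductal_panel, None, score_margin=0.0,
                               seed=cfg.seed)
        runner.write_frame(kept.cell_meta[[]], "selected_cells.tsv")

        stage = "score_axes"
        axis_scores = score_axes(kept, panels, seed=cfg.seed)
        assignment = assign_axis_subtype(axis_scores, DEFAULT_AXIS_TO_LABEL)
        kept.cell_meta["subtype"] = assignment["subtype"]
        runner.write_frame(axis_scores, "axis_scores.tsv")
        runner.write_frame(assignment, "subtype_assignment.tsv")
        runner.provenance(stage, {"n_axes": axis_scores.shape[1]}, [],
                          [runner.outdir / "axis_scores.tsv"])

        stage = "activity"
        act = infer_activity(kept, regulon)
        pc1 = first_pc(kept.lognorm, n_hvg=cfg.n_hvg)
        resid = residualize_activity(act, kept.cell_meta, pc1)
        runner.write_frame(act.values, "activity.tsv")
        runner.write_frame(resid.values, "activity_residualized.tsv")
        runner.provenance(stage, {"covariates": list(resid.covariates_used)}, [],
                          [runner.outdir / "activity_residualized.tsv"])
        activity = resid.values[cfg.tf_name].to_numpy()

        stage = "embed"
        structure, axis_pcs = compute_pc_spaces(kept, axis_scores, n_hvg=cfg.n_hvg,
                                                n_pcs=cfg.n_pcs)
        tuned = tune_combined_embedding(
            structure, axis_pcs,
            kept.cell_meta["subtype"].to_numpy(),
            kept.cell_meta["sample"].to_numpy(),
            seed=cfg.seed,
        )
        runner.write_frame(tuned.objective_curve, "embedding_objective.tsv", index=False)
        pcs_frame = pd.DataFrame(
            tuned.combined_pcs, index=kept.cell_ids,
            columns=[f"PC{i + 1}" for i in range(tuned.combined_pcs.shape[1])],
        )
        runner.write_frame(pcs_frame, "combined_pcs.tsv")
        runner.provenance(stage, {"alpha": tuned.alpha}, [],
                          [runner.outdir / "combined_pcs.tsv"])

        stage = "hurdle"
        detected = (kept.counts > 0).sum(axis=0)
        eligible = [g for g, d in zip(kept.genes, detected)
                    if d >= cfg.min_pos and g != cfg.tf_name]
        genes = eligible[: cfg.hurdle_max_genes]
        results = HurdleModel(
            kept, activity, covariates=EXOCRINE_COVARIATES, genes=genes,
            min_pos=cfg.min_pos, weights=(1.0, 1.0), clip=cfg.clip,
        ).fit()
        results.to_tsv(runner.outdir / "hurdle_results.tsv")
        results.export_rank_file(runner.outdir / "exocrine.rnk")
        runner.provenance(stage, {"n_genes": len(genes), "weights": [1, 1]}, [],
                          [runner.outdir / "hurdle_results.tsv", runner.outdir / "exocrine.rnk"])

        stage = "modules"
        from .scoring import module_score

        module_scores = pd.DataFrame(
            {
                name: module_score(kept, genes_, seed=cfg.seed + 101 + i)
                for i, (name, genes_) in enumerate(modules.sets.items())
            },
            index=kept.cell_ids,
        )
        assoc = ModuleAssociationModel(module_scores, activity, kept.cell_meta).fit()
        assoc.to_tsv(runner.outdir / "module_associations.tsv")
        runner.provenance(stage, {"modules": list(modules.sets)}, [],
                          [runner.outdir / "module_associations.tsv"])

        stage = "trajectory"
        ls = infer_pseudotime(
            tuned.combined_pcs,
            kept.cell_meta["cluster"].to_numpy() if "cluster" in kept.cell_meta.columns
            else kept.cell_meta["subtype"].to_numpy(),
            kept.cell_meta["subtype"].to_numpy(),
        )
        ls = compute_lineage_metrics(ls, kept.cell_meta["subtype"].to_numpy())
        k = min(cfg.n_lineages, len(ls.metrics.dropna()))
        ls = select_representative_lineages(ls, k=max(k, 1))
        runner.write_frame(ls.metrics, "lineage_metrics.tsv")
        runner.write_frame(ls.pseudotime, "pseudotime.tsv")
        profiles = activity_composition_profile(
            ls, activity, kept.cell_meta["subtype"].to_numpy()
        )
        prof_frames = []
        for name, frame in profiles.items():
            frame = frame.copy()
            frame.insert(0, "lineage", name)
            prof_frames.append(frame.reset_index())
        runner.write_frame(pd.concat(prof_frames, ignore_index=True),
                           "lineage_profiles.tsv", index=False)
        selection = pd.DataFrame({"lineage": ls.selected})
        runner.write_frame(selection, "selected_lineages.tsv", index=False)
        runner.provenance(stage, {"root": str(ls.root_cluster), "selected": ls.selected},
                          [], [runner.outdir / "lineage_metrics.tsv"])
    except PipelineError:
        raise
    except Exception as exc:  # surface the failing stage; keep prior outputs
        raise PipelineError(stage, exc) from exc


def _run_tumor(runner: _Runner) -> None:
    cfg = runner.cfg
    stage = "simulate"
    try:
        if cfg.matrix_path is None:
            # the fixed tumor QC preset requires >= 500 detected genes, so
            # the simulated gene universe must be comfortably larger
            m, truth = generate_tumor_dataset(
                n_cells=cfg.n_cells, seed=cfg.seed, n_genes=max(cfg.n_genes, 1500)
            )
            out = runner.outdir
            psio.write_counts_mtx(m, out / "matrix.mtx", out / "genes.tsv",
                                  out / "barcodes.tsv")
            runner.write_frame(m.cell_meta, "cell_meta.tsv")
            runner.write_frame(
                pd.DataFrame({"p_classical_true": truth.p_classical_true,
                              "family_true": truth.family_true}),
                "truth.tsv",
            )
            from .simulate import default_tumor_signatures

            signatures = default_tumor_signatures()
            psio.write_gene_sets(signatures, out / "signatures.gmt")
            runner.provenance(stage, {"n_cells": cfg.n_cells}, [], [out / "matrix.mtx"])
        else:
            m, _, _, _, _ = _load_inputs(runner)
            signatures = psio.read_gene_sets(cfg.signatures_path, "nmf_signature")

        stage = "qc"
        kept, report = apply_qc_filter(m, QCThresholds.tumor())
        runner.write_frame(report.to_frame(), "qc_report.tsv")
        runner.provenance(stage, {"preset": "tumor"}, [], [runner.outdir / "qc_report.tsv"])

        stage = "classify"
        calls = score_signatures(kept, signatures)
        runner.write_frame(calls, "family_calls.tsv")
        kept.cell_meta["cluster"] = calls["family"]
        runner.provenance(stage, {"thresholds": [0.60, 0.30]}, [],
                          [runner.outdir / "family_calls.tsv"])

        stage = "activity"
        if runner.cfg.regulon_path:
            regulon = psio.read_regulon(runner.cfg.regulon_path)
        else:
            universe = [g for g in kept.genes if not any(
                g in signatures[s] for s in signatures.names)]
            regulon = generate_regulon(cfg.tf_name, 50, 0.25, seed=cfg.seed,
                                       gene_universe=universe)
            psio.write_regulon(regulon, runner.outdir / "regulon.tsv")
        act = infer_activity(kept, regulon)
        pc1 = first_pc(kept.lognorm, n_hvg=cfg.n_hvg)
        resid = residualize_activity(act, kept.cell_meta, pc1)
        runner.write_frame(resid.values, "activity_residualized.tsv")
        runner.provenance(stage, {"covariates": list(resid.covariates_used)}, [],
                          [runner.outdir / "activity_residualized.tsv"])
        activity = resid.values[cfg.tf_name].to_numpy()

        stage = "hurdle"
        detected = (kept.counts > 0).sum(axis=0)
        eligible = [g for g, d in zip(kept.genes, detected)
                    if d >= cfg.min_pos and g != cfg.tf_name]
        genes = eligible[: cfg.hurdle_max_genes]
        results = HurdleModel(
            kept, activity, covariates=TUMOR_COVARIATES, genes=genes,
            min_pos=cfg.min_pos, weights=(2.0, 1.0), clip=cfg.clip,
        ).fit()
        results.to_tsv(runner.outdir / "hurdle_results.tsv")
        results.export_rank_file(runner.outdir / "tumor.rnk")
        runner.provenance(stage, {"n_genes": len(genes), "weights": [2, 1]}, [],
                          [runner.outdir / "hurdle_results.tsv", runner.outdir / "tumor.rnk"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
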