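"""End-to-end orchestration: simulate -> behavior -> RDMs -> first-order RSA
-> second-order RSA -> dimensionality -> preservation index.

A :class:`PipelineConfig` (JSON-serializable) names either an input directory
holding the canonical on-disk layout (``patterns/<subject>/<roi>/<cond>.tsv``,
``images.csv``, ``rois.csv``, ``behavior.csv``) or a simulation config, plus
the analysis thresholds.  ``run_pipeline`` executes every stage, writes tidy
CSV/TSV artifacts under the output directory, and records a manifest (config
hash, seed, per-stage row counts) so repeated seeded runs can be verified to
be byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import dimensionality as dim_mod
from . import preservation as pi_mod
from . import second_order_rsa as so_mod
from .first_order_rsa import (
    DEFAULT_CONTRASTS,
    category_information_test,
    disambiguation_vs_repetition,
    mds_embed,
    run_contrast,
)
from .rdm_core import (
    CONDITIONS,
    RDM,
    PatternDataset,
    ROIInfo,
    compute_rdm,
    group_average,
    write_rdm,
)
from .stats_core import StatResult, attach_fdr
from .synthetic_data import SimulationConfig, generate_behavior, generate_patterns, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "behavior", "rdm", "rsa1", "rsa2", "dims", "pi")

__all__ = ["PipelineConfig", "run_pipeline", "read_pattern_dataset", "STAGES"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full pipeline run."""

    output_dir: str = "mooneyrsa_out"
    input_dir: str | None = None          # existing dataset; None -> simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    # analysis thresholds (study defaults)
    pre_not_recognized_max: int = 2       # <=2 of 6 "yes" -> pre not-recognized
    recognized_min: int = 4               # >=4 of 6 "yes" -> recognized
    r2_threshold: float = 0.90            # MDS goodness-of-fit criterion
    mds_dims: tuple[int, int] = (2, 10)   # tested dimensionality range
    mds_restarts: int = 1
    alpha: float = 0.05
    equate_roi_sizes: int | None = None   # subsample every ROI to this many voxels
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold must lie in (0, 1], got {self.r2_threshold}")
        lo, hi = self.mds_dims
        if not 1 <= lo <= hi:
            raise ValueError(f"mds_dims must be an increasing range, got {self.mds_dims}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        self.simulation.validate()

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        sim_raw = raw.pop("simulation", {})
        rois_raw = sim_raw.pop("rois", None)
        sim = SimulationConfig(**sim_raw)
        if rois_raw is not None:
            sim.rois = [ROIInfo(**r) for r in rois_raw]
        for key in ("mds_dims", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def read_pattern_dataset(input_dir: str | Path) -> PatternDataset:
    """Load the canonical on-disk layout into a :class:`PatternDataset`."""
    input_dir = Path(input_dir)
    images = pd.read_csv(input_dir / "images.csv", dtype={"image_id": str})
    rois_df = pd.read_csv(input_dir / "rois.csv")
    rois = {
        r["name"]: ROIInfo(r["name"], r["network"], int(r["n_voxels"]),
                           int(r["latent_dim"]) if pd.notna(r.get("latent_dim")) else None)
        for r in rois_df.to_dict("records")
    }
    image_ids = images["image_id"].tolist()
    categories = dict(zip(images["image_id"], images["category"]))
    patterns: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    pattern_root = input_dir / "patterns"
    if not pattern_root.exists():
        raise FileNotFoundError(f"pattern directory not found: {pattern_root}")
    subjects = sorted(p.name for p in pattern_root.iterdir() if p.is_dir())
    for subject in subjects:
        for roi in rois:
            roi_dir = pattern_root / subject / roi
            if not roi_dir.exists():
                raise FileNotFoundError(f"missing ROI directory: {roi_dir}")
            conds = {}
            for cond in CONDITIONS:
                df = pd.read_csv(roi_dir / f"{cond}.tsv", sep="\t", index_col="image_id")
                conds[cond] = df.loc[image_ids].to_numpy(dtype=float)
            patterns[(subject, roi)] = conds
    dataset = PatternDataset(subjects=subjects, rois=rois, image_ids=image_ids,
                             categories=categories, patterns=patterns)
    dataset.validate()
    return dataset


def _results_frame(results: list[StatResult], **extra) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_dict() for r in results])
    for key, val in extra.items():
        frame.insert(0, key, val)
    return frame


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the configured stages and write all artifacts.

    Returns a context dict with the in-memory results of each stage; the
    manifest is written last so its presence marks a completed run.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }
    ctx: dict[str, object] = {}
    for stage in config.stages:
        logger.info("stage %s: starting", stage)
        try:
            rows = _STAGE_FUNCS[stage](config, out, ctx)
        except Exception as exc:
            manifest["failed_stage"] = stage
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"rows": rows}
        logger.info("stage %s: done (%s rows)", stage, rows)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    ctx["manifest"] = manifest
    return ctx


def _stage_simulate(config: PipelineConfig, out: Path, ctx: dict) -> int:
    if config.input_dir is not None:
        dataset = read_pattern_dataset(config.input_dir)
        behavior = pd.read_csv(Path(config.input_dir) / "behavior.csv",
                               dtype={"image_id": str})
        ctx["dataset"], ctx["behavior"] = dataset, behavior
        return len(dataset.subjects)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    dataset, truth = generate_patterns(sim)
    behavior = generate_behavior(sim, truth)
    write_dataset(dataset, truth, behavior, out / "data")
    ctx["dataset"], ctx["truth"], ctx["behavior"] = dataset, truth, behavior
    return len(dataset.subjects)


def _require(ctx: dict, key: str, stage: str) -> object:
    if key not in ctx:
        raise ValueError(f"stage {stage!r} requires {key!r}; run earlier stages first")
    return ctx[key]


def _stage_behavior(config: PipelineConfig, out: Path, ctx: dict) -> int:
    table = _require(ctx, "behavior", "behavior")
    summary = behavior_mod.recognition_summary(table)
    classification = behavior_mod.classify_images(
        table, n_presentations=config.simulation.n_presentations)
    anova = behavior_mod.behavior_anova(table)
    _write_csv(summary["by_stage"], out / "behavior_summary.csv")
    _write_csv(summary["by_presentation"], out / "behavior_by_presentation.csv")
    _write_csv(classification, out / "image_classification.csv")
    frames = [_results_frame(anova["effects"], analysis="anova")]
    for stage_name, results in anova["posthoc"].items():
        frames.append(_results_frame(results, analysis=f"posthoc_{stage_name}"))
    _write_csv(pd.concat(frames, ignore_index=True), out / "behavior_anova.csv")
    ctx["classification"] = classification
    ctx["image_sets"] = behavior_mod.image_sets(classification)
    ctx["behavior_summary"] = summary
    ctx["behavior_anova"] = anova
    return len(classification)


def _stage_rdm(config: PipelineConfig, out: Path, ctx: dict) -> int:
    dataset: PatternDataset = _require(ctx, "dataset", "rdm")
    if config.equate_roi_sizes is not None:
        from .rdm_core import subsample_voxels
        dataset = subsample_voxels(dataset, config.equate_roi_sizes, seed=config.seed)
    rdms: dict[tuple[str, str], RDM] = {}
    for (subject, roi), conds in dataset.patterns.items():
        rdm = compute_rdm(conds, dataset.image_ids, dataset.categories)
        rdms[(subject, roi)] = rdm
        path = out / "rdms" / f"{subject}_{roi}.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        write_rdm(rdm, path)
    ctx["rdms"] = rdms
    ctx["networks"] = dataset.networks()
    group: dict[str, RDM] = {}
    for roi in dataset.rois:
        group[roi] = group_average([rdms[(s, roi)] for s in dataset.subjects])
        write_rdm(group[roi], out / "rdms" / f"group_{roi}.tsv")
    ctx["group_rdms"] = group
    return len(rdms)


def _stage_rsa1(config: PipelineConfig, out: Path, ctx: dict) -> int:
    rdms = _require(ctx, "rdms", "rsa1")
    image_sets = ctx.get("image_sets", {})
    rois = sorted({roi for (_, roi) in rdms})
    subjects = sorted({s for (s, _) in rdms})
    all_rows: list[pd.DataFrame] = []
    # main contrasts, FDR across ROIs within each contrast family
    for spec in DEFAULT_CONTRASTS:
        per_roi: list[StatResult] = []
        for roi in rois:
            roi_rdms = {s: rdms[(s, roi)] for s in subjects}
            res, _ = run_contrast(roi_rdms, spec)
            res.label = roi
            per_roi.append(res)
        per_roi = attach_fdr(per_roi, family=spec.name)
        frame = _results_frame(per_roi, contrast=spec.name).rename(columns={"label": "roi"})
        all_rows.append(frame)
    # category information per condition, FDR across ROIs within condition
    for cond in CONDITIONS:
        per_roi = []
        for roi in rois:
            roi_rdms = {s: rdms[(s, roi)] for s in subjects}
            res, _ = category_information_test(roi_rdms, cond)
            res.label = roi
            per_roi.append(res)
        per_roi = attach_fdr(per_roi, family=f"category_information_{cond}")
        frame = _results_frame(per_roi, contrast=f"category_information_{cond}")
        all_rows.append(frame.rename(columns={"label": "roi"}))
    contrasts = pd.concat(all_rows, ignore_index=True)
    _write_csv(contrasts, out / "rsa1_contrasts.csv")
    ctx["rsa1_contrasts"] = contrasts
    # repetition control
    if image_sets:
        rows = []
        for roi in rois:
            roi_rdms = {s: rdms[(s, roi)] for s in subjects}
            try:
                per_roi_ctrl = disambiguation_vs_repetition(roi_rdms, image_sets)
            except ValueError as exc:
                logger.warning("repetition control for %s skipped: %s", roi, exc)
                continue
            for name, res in per_roi_ctrl.items():
                row = res["interaction"].to_dict()
                row.update({"roi": roi, "contrast": name,
                            "n_subjects": res["n_subjects"]})
                rows.append(row)
        if rows:
            control_df = pd.DataFrame(rows)
            _write_csv(control_df, out / "rsa1_repetition_control.csv")
            ctx["repetition_control"] = control_df
    # 2-D MDS of each ROI's group RDM (visualization coordinates)
    group_rdms: dict[str, RDM] = ctx["group_rdms"]
    coord_rows = []
    for roi, rdm in group_rdms.items():
        sol = mds_embed(rdm.values, n_dims=2, seed=config.seed,
                        restarts=config.mds_restarts)
        for (cond, image_id), (x, y) in zip(rdm.labels(), sol.coordinates):
            coord_rows.append({"roi": roi, "condition": cond, "image_id": image_id,
                               "dim1": x, "dim2": y, "stress": sol.stress,
                               "r2": sol.r_squared})
    _write_csv(pd.DataFrame(coord_rows), out / "rsa1_mds_coords.csv")
    return len(contrasts)


def _stage_rsa2(config: PipelineConfig, out: Path, ctx: dict) -> int:
    group_rdms = _require(ctx, "group_rdms", "rsa2")
    networks = ctx["networks"]
    rows = 0
    ctx["second_order"] = {}
    for scope in so_mod.SCOPES:
        so = so_mod.second_order_rdm(group_rdms, scope=scope, networks=networks)
        so.to_frame().to_csv(out / f"second_order_rdm_{scope}.tsv", sep="\t",
                             float_format="%.10g")
        sol = so_mod.embed_hierarchy(so, seed=config.seed, restarts=config.mds_restarts)
        table = so_mod.hierarchy_table(so, sol)
        _write_csv(table, out / f"hierarchy_coords_{scope}.csv")
        ctx["second_order"][scope] = {"rdm": so, "solution": sol, "table": table}
        rows += len(table)
    return rows


def _stage_dims(config: PipelineConfig, out: Path, ctx: dict) -> int:
    rdms = _require(ctx, "rdms", "dims")
    lo, hi = config.mds_dims
    results = dim_mod.dataset_dimensionality(
        rdms, ctx["networks"], threshold=config.r2_threshold,
        dims=range(lo, hi + 1), seed=config.seed, restarts=config.mds_restarts)
    _write_csv(results, out / "dimensionality.csv")
    anova = dim_mod.network_condition_anova(results)
    frames = [_results_frame(anova["effects"], analysis="anova")]
    for factor, res_list in anova["posthoc"].items():
        frames.append(_results_frame(res_list, analysis=f"posthoc_{factor}"))
    _write_csv(pd.concat(frames, ignore_index=True), out / "dimensionality_anova.csv")
    ctx["dimensionality"] = results
    ctx["dimensionality_anova"] = anova
    return len(results)


def _stage_pi(config: PipelineConfig, out: Path, ctx: dict) -> int:
    rdms = _require(ctx, "rdms", "pi")
    image_sets = _require(ctx, "image_sets", "pi")
    pis = pi_mod.dataset_pi(rdms, image_sets["disambiguation"], ctx["networks"])
    if pis.empty:
        raise ValueError("no subject has enough disambiguation-set images for a PI")
    _write_csv(pis, out / "preservation.csv")
    group = pi_mod.pi_group_tests(pis, min_subjects=min(6, pis.groupby("roi").size().min()))
    _write_csv(group, out / "preservation_group_tests.csv")
    ctx["pi"] = pis
    ctx["pi_group"] = group
    anova_frames = []
    for grouping in ("5-level", "3-level"):
        try:
            anova = pi_mod.pi_network_anova(pis, grouping=grouping)
        except ValueError as exc:
            logger.warning("PI network ANOVA (%s) skipped: %s", grouping, exc)
            continue
        frame = _results_frame(anova["effects"], analysis=f"anova_{grouping}")
        posthoc = _results_frame(anova["posthoc"], analysis=f"posthoc_{grouping}")
        anova_frames.extend([frame, posthoc])
        ctx[f"pi_anova_{grouping}"] = anova
    if anova_frames:
        _write_csv(pd.concat(anova_frames, ignore_index=True),
                   out / "preservation_network_anova.csv")
    return len(pis)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "rdm": _stage_rdm,
    "rsa1": _stage_rsa1,
    "rsa2": _stage_rsa2,
    "dims": _stage_dims,
    "pi": _stage_pi,
}
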