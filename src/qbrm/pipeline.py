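"""End-to-end orchestration: simulate -> reconstruct -> detect -> quantify -> stats.

Each stage reads its inputs from and writes its outputs to the run
directory, so stages are individually re-runnable and skippable: a stage
whose output files already exist is skipped (recorded as such in the run
manifest) unless ``force`` is given.  Any stage failure aborts downstream
stages; the manifest records the partial state.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, RunManifest
from .core import reconstruct_parameter_map, render_rgb
from .detect import (
    TilingConfig,
    TrainConfig,
    crop_training_patches,
    sliced_inference,
    train_reference_detector,
)
from .io import (
    read_boxes,
    read_rgb,
    read_roi,
    read_stack,
    write_boxes,
    write_parameter_map,
    write_rgb,
    write_roi,
    write_stack,
)
from .quantify import (
    ROI,
    build_damage_profile,
    compute_density,
    densities_to_frame,
    summarize_max_damage,
)
from .stats import detection_metrics, match_detections, one_way_anova, tukey_hsd
from .synth import (
    CohortSpec,
    SectionSimConfig,
    generate_cohort,
    generate_polarization_stack,
    generate_section_truth,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("qbrm.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; downstream stages were not run."""


def _section_config(cfg: PipelineConfig, density: float, seed: int) -> SectionSimConfig:
    s = cfg.simulate.section
    return SectionSimConfig(
        image_height_px=s.height_px,
        image_width_px=s.width_px,
        pixel_size_um=s.pixel_size_um,
        fiber_orientation_deg=s.fiber_orientation_deg,
        fiber_orientation_jitter_deg=s.fiber_orientation_jitter_deg,
        fiber_density=s.fiber_density,
        debris_density_per_mm2=density,
        debris_diameter_um_range=tuple(s.debris_diameter_um_range),
        noise_sd_frac=s.noise_sd_frac,
        illumination_angles_deg=tuple(s.illumination_angles_deg),
        seed=seed,
    )


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    manifest_csv = out / "cohort_manifest.csv"
    if manifest_csv.exists():
        manifest.record_stage("simulate", status="skipped", detail="outputs exist")
        return
    spec = CohortSpec(
        groups=[tuple(g) for g in cfg.simulate.groups],
        sections_per_animal=cfg.simulate.sections_per_animal,
        section_spacing_um=cfg.simulate.section_spacing_um,
        profile_peak_um=cfg.simulate.profile_peak_um,
        profile_fwhm_um=cfg.simulate.profile_fwhm_um,
        peak_jitter_um=cfg.simulate.peak_jitter_um,
        baseline_density_per_mm2=cfg.simulate.baseline_density_per_mm2,
        section_template=_section_config(cfg, 0.0, 0),
        seed=cfg.seed,
    )
    cohort = generate_cohort(spec, mode="images")
    (out / "stacks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    outputs = [manifest_csv]
    for (animal_id, s_idx), truth in cohort.sections.items():
        stem = f"{animal_id}_s{s_idx:02d}"
        scfg = SectionSimConfig(**truth.manifest["config"])
        stack = generate_polarization_stack(truth, scfg)
        outputs.append(write_stack(out / "stacks" / f"{stem}.tif", stack))
        outputs.append(
            write_boxes(
                out / "truth" / f"{stem}.json",
                truth.debris_boxes,
                image_size=truth.retardance_field.shape,
                image_name=stem,
            )
        )
        if not (out / "roi.json").exists():
            write_roi(out / "roi.json", truth.roi)
    cohort.manifest.to_csv(manifest_csv, index=False)
    manifest.record_stage("simulate", outputs=outputs[:4])
    log.info("simulated %d sections", len(cohort.sections))


def _stage_reconstruct(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    (out / "rgb").mkdir(exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    stacks = sorted((out / "stacks").glob("*.tif"))
    if not stacks:
        raise PipelineError("reconstruct: no stacks found")
    done = []
    for stack_path in stacks:
        rgb_path = out / "rgb" / (stack_path.stem + ".png")
        map_path = out / "maps" / (stack_path.stem + ".tif")
        if rgb_path.exists() and map_path.exists():
            continue
        stack = read_stack(stack_path)
        pmap = reconstruct_parameter_map(
            stack, retardance_floor=cfg.reconstruct.retardance_floor
        )
        write_parameter_map(map_path, pmap)
        write_rgb(rgb_path, render_rgb(pmap), bits=8)
        done.append(rgb_path)
    if done:
        manifest.record_stage("reconstruct", outputs=done[:4])
    else:
        manifest.record_stage("reconstruct", status="skipped", detail="outputs exist")


def _train_detector(cfg: PipelineConfig, rng: np.random.Generator):
    """Train the reference detector on dedicated simulated sections."""
    patches = []
    tiling = TilingConfig(tile_px=cfg.detect.tile_px, overlap_frac=cfg.detect.overlap_frac)
    for i in range(cfg.detect.train_sections):
        scfg = _section_config(
            cfg,
            cfg.detect.train_debris_density_per_mm2,
            seed=int(rng.integers(2**31)),
        )
        truth = generate_section_truth(scfg)
        stack = generate_polarization_stack(truth, scfg)
        rgb = render_rgb(reconstruct_parameter_map(stack))
        patches.extend(
            (patch, boxes) for patch, boxes, _ in crop_training_patches(
                rgb, truth.debris_boxes, tiling
            )
        )
    return train_reference_detector(patches, TrainConfig(seed=cfg.seed))


def _stage_detect(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    (out / "detections").mkdir(exist_ok=True)
    rgbs = sorted((out / "rgb").glob("*.png"))
    if not rgbs:
        raise PipelineError("detect: no reconstructed RGB images found")
    todo = [p for p in rgbs if not (out / "detections" / (p.stem + ".json")).exists()]
    if not todo:
        manifest.record_stage("detect", status="skipped", detail="outputs exist")
        return
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    detector, train_log = _train_detector(cfg, rng)
    tiling = TilingConfig(tile_px=cfg.detect.tile_px, overlap_frac=cfg.detect.overlap_frac)
    outputs = []
    n_failed = 0
    for rgb_path in todo:
        image = read_rgb(rgb_path)
        result = sliced_inference(
            image,
            detector,
            tiling,
            tta=cfg.detect.tta,
            nms_iou=cfg.detect.nms_iou,
            confidence_thr=cfg.detect.confidence_thr,
        )
        n_failed += len(result.failed_tiles)
        for tile_idx, err in result.failed_tiles:
            manifest.warnings.append(f"{rgb_path.stem}: tile {tile_idx} failed: {err}")
        outputs.append(
            write_boxes(
                out / "detections" / (rgb_path.stem + ".json"),
                result.detections,
                image_size=image.shape[:2],
                image_name=rgb_path.stem,
            )
        )
    import json

    (out / "detector_training.json").write_text(json.dumps(train_log, indent=1))
    manifest.record_stage(
        "detect",
        outputs=outputs[:4],
        detail=f"{len(outputs)} images, {n_failed} failed tiles",
    )


def _stage_quantify(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    density_csv = out / "density.csv"
    max_csv = out / "max_damage.csv"
    if density_csv.exists() and max_csv.exists():
        manifest.record_stage("quantify", status="skipped", detail="outputs exist")
        return
    cohort = pd.read_csv(out / "cohort_manifest.csv")
    roi = read_roi(out / "roi.json")
    profiles_by_group: dict[str, list] = {}
    for animal_id, animal_rows in cohort.groupby("animal_id", sort=True):
        group = animal_rows["group"].iloc[0]
        section_densities = []
        for _, row in animal_rows.iterrows():
            stem = f"{animal_id}_s{int(row.section_id):02d}"
            dets = read_boxes(out / "detections" / f"{stem}.json")
            section_densities.append(
                compute_density(
                    dets,
                    roi,
                    animal_id=animal_id,
                    section_id=int(row.section_id),
                    position_um=float(row.position_um),
                )
            )
        profile = build_damage_profile(section_densities, animal_id=animal_id, group_label=group)
        profiles_by_group.setdefault(group, []).append(profile)
    densities_to_frame(profiles_by_group).to_csv(density_csv, index=False)
    summarize_max_damage(profiles_by_group).to_csv(max_csv, index=False)
    manifest.record_stage("quantify", outputs=[density_csv, max_csv])


def _stage_stats(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    import json

    stats_csv = out / "anova_tukey.csv"
    report_json = out / "eval_report.json"
    if stats_csv.exists() and report_json.exists():
        manifest.record_stage("stats", status="skipped", detail="outputs exist")
        return
    max_table = pd.read_csv(out / "max_damage.csv")
    groups = {
        g: rows["max_density_per_mm2"].tolist()
        for g, rows in max_table.groupby("group")
    }
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, alpha=cfg.stats.alpha)
    tukey.insert(0, "anova_F", anova.F)
    tukey.insert(1, "anova_p", anova.p)
    tukey.to_csv(stats_csv, index=False)

    # pooled detector evaluation against simulated ground truth
    roi = read_roi(out / "roi.json")
    tp = fp = fn = 0
    area = 0.0
    for det_path in sorted((out / "detections").glob("*.json")):
        truth_path = out / "truth" / det_path.name
        if not truth_path.exists():
            continue
        match = match_detections(
            read_boxes(det_path),
            [d.box for d in read_boxes(truth_path)],
            cfg.stats.match_iou,
        )
        rep = detection_metrics(match)
        tp, fp, fn = tp + rep.tp, fp + rep.fp, fn + rep.fn
        area += roi.area_mm2
    report = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "fp_fraction": fp / (tp + fp) if tp + fp else None,
        "fp_per_mm2": fp / area if area else None,
        "evaluated_area_mm2": area,
    }
    report_json.write_text(json.dumps(report, indent=1))
    manifest.record_stage("stats", outputs=[stats_csv, report_json])


_STAGES = [
    ("simulate", _stage_simulate),
    ("reconstruct", _stage_reconstruct),
    ("detect", _stage_detect),
    ("quantify", _stage_quantify),
    ("stats", _stage_stats),
]


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run all stages in order, emitting a run manifest.

    Stages whose outputs already exist are skipped, which makes partial
    re-runs cheap.  A stage failure raises :class:`PipelineError` after
    writing the manifest with the partial state.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), software_version=__version__)
    manifest_path = out / "run_manifest.json"
    for name, stage in _STAGES:
        try:
            stage(cfg, out, manifest)
        except Exception as exc:
            manifest.record_stage(name, status="failed", detail=repr(exc))
            manifest.write(manifest_path)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    manifest.write(manifest_path)
    return manifest
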