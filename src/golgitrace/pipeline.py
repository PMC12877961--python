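"""End-to-end orchestration: denoise → extract → repair → skeletonize → measure.

:func:`run_pipeline` executes the full reconstruction on one volume plus a
marker file and writes a reproducible output bundle: raw-stage and revised
SWC trees, stage masks, the per-terminal repair report, morphometry and
Sholl CSVs, a raw-vs-revised comparison, the exact configuration used and
a structured per-stage log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import gap_repair, morphometry, segmentation, volio
from .config import PipelineConfig
from .gap_repair import TraceCostParams
from .volio import Volume


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineResult:
    raw_tree: volio.SWCTree
    revised_tree: volio.SWCTree
    comparison: morphometry.ComparisonReport
    repair_report: "object"
    out_dir: Path
    log: list[str]


def _mask_volume(mask: segmentation.BinaryMask) -> Volume:
    return Volume((mask.grid * np.uint8(255)), mask.spacing, 8)


def run_pipeline(
    volume_path: str | Path,
    markers_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> PipelineResult:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(stage: str, msg: str) -> None:
        log.append(f"[{stage}] {msg}")

    # --- load --------------------------------------------------------------
    try:
        vol = volio.read_volume(volume_path, config.spacing)
    except volio.FormatError as exc:
        raise StageError("load", f"volume {volume_path}: {exc}") from exc
    try:
        markers = volio.read_markers(markers_path, require_soma=True)
        soma = markers.single_soma()
    except volio.FormatError as exc:
        raise StageError("load", f"markers {markers_path}: {exc}") from exc
    note("load", f"volume shape {vol.shape}, bit depth {vol.bit_depth}, "
                 f"{len(markers)} markers ({len(markers.terminals)} terminals)")

    if vol.bit_depth == 16:
        vol = volio.convert_to_8bit(vol)
        note("load", "converted 16-bit volume to 8-bit (min-max scaling)")

    # --- denoise -----------------------------------------------------------
    try:
        mask = segmentation.threshold_volume(vol, config.threshold, config.polarity)
    except ValueError as exc:
        raise StageError("denoise", str(exc)) from exc
    note("denoise", f"threshold {config.threshold}: {mask.n_foreground} foreground voxels")
    mask = segmentation.apply_edits(mask, markers)
    note("denoise", f"after eraser edits: {mask.n_foreground} voxels "
                    f"({len(markers.erasers)} erasers)")

    # --- extract -----------------------------------------------------------
    try:
        lab = segmentation.label_components(mask, config.connectivity)
        note("extract", f"{lab.n_components} components before volume filter")
        filtered = segmentation.filter_small_components(lab, config.min_volume)
        lab2 = segmentation.label_components(filtered, config.connectivity)
        note("extract", f"{lab2.n_components} components ≥ {config.min_volume} μm³")
        raw_mask = segmentation.select_neuron(lab2, soma.position, config.snap_radius)
    except (segmentation.SeedError, ValueError) as exc:
        raise StageError("extract", str(exc)) from exc
    note("extract", f"soma component: {raw_mask.n_foreground} voxels")

    params = TraceCostParams(lambda_=config.lambda_, gamma=config.gamma)

    # --- raw-stage skeleton ------------------------------------------------
    try:
        raw_tree = morphometry.skeletonize_to_swc(
            raw_mask, vol, soma.position, params,
            prune_um=config.prune_um, resample_um=config.resample_um,
            radius_threshold=config.threshold,
        )
    except ValueError as exc:
        raise StageError("skeletonize", f"raw stage: {exc}") from exc
    note("skeletonize", f"raw tree: {raw_tree.n_nodes} nodes")

    # --- repair ------------------------------------------------------------
    repair = gap_repair.repair_neuron(
        raw_mask, vol, markers, params,
        threshold=config.threshold, cap_factor=config.cap_factor,
    )
    n_ok = int((repair.report["status"] == "repaired").sum())
    n_fail = int((repair.report["status"] == "failed").sum())
    note("repair", f"{n_ok} terminals repaired, {n_fail} failed, "
                   f"{len(repair.report) - n_ok - n_fail} already connected")
    try:
        lab3 = segmentation.label_components(repair.mask, config.connectivity)
        revised_mask = segmentation.select_neuron(lab3, soma.position, config.snap_radius)
    except segmentation.SeedError as exc:
        raise StageError("repair", str(exc)) from exc
    note("repair", f"revised component: {revised_mask.n_foreground} voxels")

    try:
        revised_tree = morphometry.skeletonize_to_swc(
            revised_mask, vol, soma.position, params,
            prune_um=config.prune_um, resample_um=config.resample_um,
            radius_threshold=config.threshold,
        )
    except ValueError as exc:
        raise StageError("skeletonize", f"revised stage: {exc}") from exc
    note("skeletonize", f"revised tree: {revised_tree.n_nodes} nodes")

    # --- morphometry -------------------------------------------------------
    comparison = morphometry.compare_morphometry(
        raw_tree, revised_tree, sholl_step=config.sholl_step
    )
    note("morphometry",
         f"branch count {comparison.raw.branch_count} → {comparison.revised.branch_count}, "
         f"total length {comparison.raw.total_length:.1f} → "
         f"{comparison.revised.total_length:.1f} μm")

    # --- write bundle ------------------------------------------------------
    volio.write_swc(raw_tree, out_dir / "raw.swc")
    volio.write_swc(revised_tree, out_dir / "revised.swc")
    volio.write_volume(_mask_volume(raw_mask), out_dir / "raw_mask.tif")
    volio.write_volume(_mask_volume(revised_mask), out_dir / "revised_mask.tif")
    repair.report.to_csv(out_dir / "repair_report.csv", index=False)
    comparison.to_frame().to_csv(out_dir / "comparison.csv", index=False)
    comparison.raw.sholl.to_frame().to_csv(out_dir / "sholl_raw.csv", index=False)
    comparison.revised.sholl.to_frame().to_csv(out_dir / "sholl_revised.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "comparison.txt", "w") as fh:
        fh.write(render_comparison(comparison))
    with open(out_dir / "pipeline.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            {
                "raw": comparison.raw.to_dict(),
                "revised": comparison.revised.to_dict(),
                "percent_change": comparison.percent_change,
                "fold_change": comparison.fold_change,
            },
            fh, indent=2,
        )
    return PipelineResult(
        raw_tree=raw_tree,
        revised_tree=revised_tree,
        comparison=comparison,
        repair_report=repair.report,
        out_dir=out_dir,
        log=log,
    )


def render_comparison(cmp: morphometry.ComparisonReport) -> str:
    """Human-readable raw-vs-revised summary."""
    lines = ["metric                     raw      revised   %change   fold"]
    raw_d, rev_d = cmp.raw.to_dict(), cmp.revised.to_dict()
    for metric in sorted(set(raw_d) | set(rev_d)):
        a = raw_d.get(metric, 0)
        b = rev_d.get(metric, 0)
        pc = cmp.percent_change.get(metric)
        fc = cmp.fold_change.get(metric)
        pc_s = f"{pc:+d}%" if pc is not None else "n/a"
        fc_s = f"{fc:.1f}x" if fc is not None else "n/a"
        lines.append(f"{metric:<25} {a:>8.1f} {b:>10.1f} {pc_s:>9} {fc_s:>6}")
    return "\n".join(lines) + "\n"
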