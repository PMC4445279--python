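"""End-to-end orchestration of the detection/splitting/validation pipeline.

Stage order: RATS overmask -> masked local maxima -> model classification
-> mean-shift refinement -> merging (model output); RATS segmask ->
26-connected components -> marker-guided clump splitting (refined
centers); optional morphology co-localization of both marker sets;
quantification; optional evaluation against reference annotations.

All randomness flows from one seed (training); detection itself is
deterministic.  Every run can write its artifacts (marker CSVs, label
TIFF, stats CSV, manifest JSON) to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from puncta3d.core import MarkerSet, VolumeStack, write_labels, write_markers
from puncta3d.detection import (
    DetectionParams,
    classify_candidates,
    local_maxima,
    mean_shift_refine,
    merge_close,
)
from puncta3d.evaluation import EvalReport, f_measure, precision_recall, match_markers, region_report
from puncta3d.learning import AlgorithmChain, MlpConfig, TrainedModel, chain_features, roi_labels, train_mlp
from puncta3d.rats import RatsParams, calibrate_params, overmask_params, rats_mask_pseudo3d
from puncta3d.splitting import LabeledObjects, connected_components_26, quantify, split_objects
from puncta3d.validation import colocalize_filter, morphology_foreground

__all__ = ["PipelineResult", "train_chain_model", "detect_markers", "run_pipeline"]


@dataclass
class PipelineResult:
    model_markers: MarkerSet  # model output: classified + shifted + merged (+ validated)
    refined_markers: MarkerSet  # after marker-guided splitting (+ validated)
    objects: LabeledObjects  # split label grid
    stats: dict  # quantification summary
    counts: dict  # per-stage marker/object counts
    model: TrainedModel
    report_model: EvalReport | None = None
    report_refined: EvalReport | None = None


def train_chain_model(
    rois,
    chain: AlgorithmChain | None = None,
    mlp_config: MlpConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the default haar3d + MLP chain on a labeled ROI set."""
    chain = chain or AlgorithmChain()
    cfg = mlp_config or MlpConfig(seed=seed)
    X = chain_features(chain, rois)
    y = roi_labels(rois)
    return train_mlp(X, y, cfg, chain=chain)


def detect_markers(
    synapse: VolumeStack,
    model: TrainedModel,
    rats_params: RatsParams | None = None,
    det: DetectionParams = DetectionParams(),
) -> tuple[MarkerSet, dict]:
    """Model output markers: overmask -> maxima -> classify -> shift -> merge."""
    rp = rats_params or calibrate_params(synapse)
    over = rats_mask_pseudo3d(synapse, overmask_params(rp))
    cand = local_maxima(synapse, over, det.maxima_neighborhood)
    cls = classify_candidates(model, synapse, cand, det.roi_size)
    shifted = MarkerSet(
        mean_shift_refine(synapse, m, det.shift_window, det.shift_tol, det.shift_max_iter)
        for m in cls
    )
    merged = merge_close(shifted, det.min_sep, z_scale=synapse.z_anisotropy)
    counts = {
        "overmask_voxels": int(over.sum()),
        "candidates": len(cand),
        "classified": len(cls),
        "model_markers": len(merged),
    }
    return merged, counts


def run_pipeline(
    synapse: VolumeStack,
    morphology: VolumeStack | None = None,
    model: TrainedModel | None = None,
    training_rois=None,
    reference: MarkerSet | None = None,
    rats_params: RatsParams | None = None,
    morph_rats_params: RatsParams | None = None,
    det: DetectionParams = DetectionParams(),
    eval_box: tuple[int, int, int] = (7, 7, 5),
    coloc_box: tuple[int, int, int] = (9, 9, 5),
    seg_opening: tuple[int, int, int] | None = (1, 3, 3),
    seed: int = 0,
    outdir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run every stage in order and (optionally) write artifacts.

    Either a trained ``model`` or labeled ``training_rois`` must be given.
    The morphology channel is optional; without it the co-localization
    stage is skipped.
    """
    if model is None:
        if training_rois is None:
            raise ValueError("either a trained model or training ROIs are required")
        model = train_chain_model(training_rois, seed=seed)
    if morphology is not None and morphology.shape != synapse.shape:
        raise ValueError(f"channel shape mismatch: {synapse.shape} vs {morphology.shape}")

    rp = rats_params or calibrate_params(synapse)
    model_markers, counts = detect_markers(synapse, model, rp, det)

    seg = rats_mask_pseudo3d(synapse, rp)
    if seg_opening is not None:
        # in-plane opening: removes speckle and cuts 1-2 px noise bridges
        # between puncta without eroding punctum cores across slices
        seg = ndimage.binary_opening(seg, structure=np.ones(seg_opening, dtype=bool))
    objects = connected_components_26(seg)
    counts["segmented_objects"] = objects.n_objects
    split_lab, refined = split_objects(objects, model_markers, z_scale=synapse.z_anisotropy)
    counts["split_objects"] = split_lab.n_objects
    counts["refined_markers"] = len(refined)

    if morphology is not None:
        mrp = morph_rats_params or calibrate_params(morphology)
        mmask = morphology_foreground(morphology, mrp)
        model_markers = colocalize_filter(model_markers, mmask, coloc_box)
        refined = colocalize_filter(refined, mmask, coloc_box)
        counts["model_markers_validated"] = len(model_markers)
        counts["refined_markers_validated"] = len(refined)

    stats = quantify(split_lab)
    report_model = report_refined = None
    if reference is not None:
        z_scale = synapse.z_anisotropy
        report_model = region_report([(model_markers, reference)], box=eval_box, z_scale=z_scale)
        report_refined = region_report([(refined, reference)], box=eval_box, z_scale=z_scale)

    result = PipelineResult(
        model_markers=model_markers,
        refined_markers=refined,
        objects=split_lab,
        stats=stats,
        counts=counts,
        model=model,
        report_model=report_model,
        report_refined=report_refined,
    )
    if outdir is not None:
        _write_artifacts(result, rp, det, seed, outdir)
    return result


def _write_artifacts(result: PipelineResult, rp: RatsParams, det: DetectionParams,
                     seed: int, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_markers(result.model_markers, os.path.join(outdir, "model_markers.csv"))
    write_markers(result.refined_markers, os.path.join(outdir, "refined_markers.csv"))
    write_labels(result.objects.labels, os.path.join(outdir, "split_labels.tif"))
    rows = [
        {"label": s.label, "voxel_count": s.voxel_count,
         "centroid_z": s.centroid[0], "centroid_y": s.centroid[1], "centroid_x": s.centroid[2],
         "n_markers": s.n_markers, "unsplittable": s.unsplittable}
        for s in result.objects.stats
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "objects.csv"), index=False)
    if result.report_model is not None:
        result.report_model.table.to_csv(os.path.join(outdir, "eval_model.csv"), index=False)
        result.report_refined.table.to_csv(os.path.join(outdir, "eval_refined.csv"), index=False)
    config = {"rats": asdict(rp), "detection": asdict(det), "seed": seed}
    manifest = {
        "config": config,
        "config_hash": hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        "counts": result.counts,
        "quantification": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in result.stats.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
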