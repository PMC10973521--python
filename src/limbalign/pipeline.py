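"""End-to-end orchestration: masks -> landmarks -> axes -> angles, and the
desk-scale two-step segmentation experiment on phantom populations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import alignment, metrics, phantom, segmentation as seg
from .landmarks import BONE_NAMES, LimbMasks, extract_landmarks


def measure_leg(
    masks: LimbMasks,
    varus_threshold: float = 3.0,
    mtfa_convention: str = "varus_gt_180",
) -> Dict:
    """One leg's full measurement report from its five bone masks."""
    landmarks = extract_landmarks(masks)
    axes = alignment.build_axes(landmarks)
    angles = alignment.compute_angles(axes, masks.side, mtfa_convention)
    return {
        "side": masks.side,
        "landmarks": {k: list(v) for k, v in landmarks.as_dict().items()},
        "angles": angles.as_dict(),
        "classification": alignment.classify_alignment(angles, varus_threshold),
        "quality_flags": angles.quality_flags(),
    }


# ---------------------------------------------------------------------------
# Desk-scale two-step segmentation experiment
# ---------------------------------------------------------------------------


@dataclass
class SegmentationExperiment:
    """Held-out evaluation of the two-step pipeline trained on phantoms."""

    per_bone_dsc: Dict[str, float]  # mean DSC per bone on the test split
    per_bone_scores: Dict[str, metrics.SegmentationScores]
    split: Tuple[int, int, int]
    histories: Dict[str, Dict[str, list]]


def stage1_training_pair(case: phantom.PhantomCase, cfg: seg.StageConfig):
    """(2-channel image, label raster) for training a step-1 ROI locator on
    one phantom case (image channel + normalised vertical coordinate)."""
    img, _ = seg.preprocess_stage1(case.image, cfg)
    w, h = cfg.stage1_size
    label = np.zeros((h, w), dtype=np.int64)
    for ci, bone in enumerate(BONE_NAMES, start=1):
        m = seg.resize(case.masks[bone].astype(np.float32), (h, w), order=0)
        label[m > 0.5] = ci
    return seg.with_coord_channel(img), label


def _truth_roi(mask: np.ndarray, margin: float) -> "seg.Box":
    from .geometry import Box

    ys, xs = np.nonzero(mask)
    x0, x1 = float(xs.min()), float(xs.max() + 1)
    y0, y1 = float(ys.min()), float(ys.max() + 1)
    mx, my = margin * (x1 - x0), margin * (y1 - y0)
    return Box(
        max(x0 - mx, 0.0),
        max(y0 - my, 0.0),
        min(x1 + mx, float(mask.shape[1])),
        min(y1 + my, float(mask.shape[0])),
    )


def _init_bias_to_priors(model: seg.SegModel, labels) -> None:
    """Set the classifier bias to the log class priors of the training
    labels.  With heavily imbalanced pixel classes this skips the long
    initial phase in which SGD only learns the background frequency."""
    counts = np.bincount(
        np.concatenate([np.asarray(l).ravel() for l in labels]),
        minlength=model.n_classes,
    ).astype(float)
    priors = counts / counts.sum()
    model.classifier.b[:] = np.log(priors + 1e-8).astype(np.float32)


def run_desk_segmentation_experiment(
    n_cases: int = 200,
    seed: int = 42,
    stage2_epochs: int = 10,
    base_spec: Optional[phantom.PhantomSpec] = None,
) -> SegmentationExperiment:
    """Train the reduced per-bone segmentation networks on a generated
    phantom population and score them on the held-out test split.

    The population is split 80/10/10 (train/validation/test).  One binary
    network per bone is trained on ROI crops around the reference masks
    (the bone's bounding box plus the configured margin, resized to the
    bone's reduced working size), following the two-step design's second
    step; predictions on the held-out crops are mapped back to raw
    coordinates and scored against the full-resolution reference masks.
    The step-1 ROI locator is exercised separately (``locate_rois``); its
    desk-scale training is not part of this evaluation.

    Training uses the standard recipe (SGD momentum 0.9, lr 1e-2, batch 4)
    with a reduced epoch count sized to the strong phantom contrast.
    """
    cfg = seg.StageConfig.desk()
    specs = phantom.sample_specs(n_cases, seed=seed, base_spec=base_spec)
    n_train = int(round(0.8 * n_cases))
    n_val = int(round(0.1 * n_cases))
    n_test = n_cases - n_train - n_val

    crops_train = {b: [] for b in BONE_NAMES}
    crops_val = {b: [] for b in BONE_NAMES}
    test_cases: List[phantom.PhantomCase] = []

    for i, sp in enumerate(specs):
        case = phantom.generate_phantom(sp)
        if i >= n_train + n_val:
            test_cases.append(case)
            continue
        dest = crops_train if i < n_train else crops_val
        for bone in BONE_NAMES:
            truth = case.masks[bone]
            roi = _truth_roi(truth, cfg.roi_margin)
            img, tf, _ = seg.crop_and_resize(case.image, roi, bone, cfg)
            lbl = seg.crop_mask(truth, tf, cfg.crop_sizes[bone]).astype(np.int64)
            dest[bone].append((img, lbl))

    histories: Dict[str, Dict[str, list]] = {}
    bone_models: Dict[str, seg.SegModel] = {}
    for bi, bone in enumerate(BONE_NAMES):
        model = seg.build_model("desk", n_classes=2, seed=seed + 1 + bi)
        _init_bias_to_priors(model, [l for _, l in crops_train[bone]])
        histories[bone] = seg.train(
            model,
            crops_train[bone],
            seg.TrainConfig(max_epochs=stage2_epochs, seed=seed + 1 + bi),
            val_dataset=crops_val[bone],
        )
        bone_models[bone] = model

    dscs = {b: [] for b in BONE_NAMES}
    scores = {b: [] for b in BONE_NAMES}
    for case in test_cases:
        for bone in BONE_NAMES:
            truth = case.masks[bone]
            roi = _truth_roi(truth, cfg.roi_margin)
            img, tf, _ = seg.crop_and_resize(case.image, roi, bone, cfg)
            pred_crop = seg.predict_mask(bone_models[bone], img)
            pred_full = seg.uncrop_mask(pred_crop, tf, truth.shape)
            dscs[bone].append(metrics.dice(pred_full, truth))
            scores[bone].append(metrics.confusion_scores(pred_full, truth))

    per_bone_dsc = {b: float(np.mean(v)) for b, v in dscs.items()}
    per_bone_scores = {}
    for bone, lst in scores.items():
        per_bone_scores[bone] = metrics.SegmentationScores(
            **{
                k: float(np.mean([s.as_dict()[k] for s in lst]))
                for k in lst[0].as_dict()
            }
        )
    return SegmentationExperiment(
        per_bone_dsc=per_bone_dsc,
        per_bone_scores=per_bone_scores,
        split=(n_train, n_val, n_test),
        histories=histories,
    )
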