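"""Viewing-condition manipulations and the model-comparison matrix.

Three test-time presentations probe what the binocular network learned:

* standard  — left/right images as rendered;
* identical — the left image occupies both input slots (no disparity, no
  half-occlusions; monocular cues intact);
* swapped   — pseudoscopic presentation: images exchanged between the
  cameras, reversing the sign of every disparity.

Ground truth always follows the presented images: under ``identical`` the
right-slot segmentation truth becomes the left labels; under ``swapped``
the slot truths are exchanged and the depth truth becomes the right-camera
depth map (the image now in the left slot), putting it in direct
opposition to disparity-defined depth.

The experiment matrix trains model variants (full binocular, binocular
without segmentation-to-depth lateral connections, segmentation-only
binocular, monocular U-net, and a binocular model trained on identical
pairs) and scores every requested (variant, training condition, test
condition) cell on the same test frames, enabling related-samples
statistics across cells.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from . import evaluation, network, training
from .scene_synth import StereoFrame

log = logging.getLogger("binoseg.experiments")

ViewingCondition = Literal["standard", "identical", "swapped"]
VIEWING_CONDITIONS = ("standard", "identical", "swapped")

TrainCondition = Literal["standard", "identical_trained", "seg_only",
                         "no_lateral", "monocular_unet"]

#: variant implied by each training condition
VARIANT_FOR_TRAIN = {
    "standard": "binocular_full",
    "identical_trained": "binocular_full",
    "seg_only": "binocular_seg_only",
    "no_lateral": "binocular_no_lateral",
    "monocular_unet": "monocular_unet",
}

#: the paper-style default matrix: standard-trained model under all three
#: presentations, identical-trained under two, plus the three ablations
DEFAULT_MATRIX = (
    ("standard", "standard"),
    ("standard", "identical"),
    ("standard", "swapped"),
    ("identical_trained", "identical"),
    ("identical_trained", "standard"),
    ("seg_only", "standard"),
    ("no_lateral", "standard"),
    ("monocular_unet", "standard"),
)


# --------------------------------------------------------------------------
# Manipulations
# --------------------------------------------------------------------------


def apply_viewing_condition(frame: StereoFrame, cond: ViewingCondition
                            ) -> StereoFrame:
    """Rearrange a stereo frame's input slots, carrying ground truth along.

    Pixel values are never altered — slots are only exchanged or
    duplicated.  ``swapped`` is an involution; ``standard`` is the
    identity (a copy).
    """
    if cond == "standard":
        return copy.deepcopy(frame)
    if cond == "identical":
        return StereoFrame(
            left_rgb=frame.left_rgb.copy(),
            right_rgb=frame.left_rgb.copy(),
            left_labels=frame.left_labels.copy(),
            right_labels=frame.left_labels.copy(),
            depth_left=frame.depth_left.copy(),
            depth_right=frame.depth_left.copy(),
        )
    if cond == "swapped":
        if frame.depth_right is None:
            raise ValueError("swapped presentation needs the right-camera "
                             "depth map")
        return StereoFrame(
            left_rgb=frame.right_rgb.copy(),
            right_rgb=frame.left_rgb.copy(),
            left_labels=frame.right_labels.copy(),
            right_labels=frame.left_labels.copy(),
            depth_left=frame.depth_right.copy(),
            depth_right=frame.depth_left.copy(),
        )
    raise ValueError(f"unknown viewing condition {cond!r}")


def condition_arrays(data: training.FrameArrays, cond: ViewingCondition
                     ) -> training.FrameArrays:
    """apply_viewing_condition over a whole stacked dataset."""
    out = copy.copy(data)
    if cond == "standard":
        return out
    if cond == "identical":
        out.right = data.left.copy()
        out.right_labels = data.left_labels.copy()
        out.depth_right = data.depth.copy()
        return out
    if cond == "swapped":
        if getattr(data, "depth_right", None) is None:
            raise ValueError("swapped presentation needs right-camera depth")
        out.left, out.right = data.right.copy(), data.left.copy()
        out.left_labels = data.right_labels.copy()
        out.right_labels = data.left_labels.copy()
        out.depth = data.depth_right.copy()
        out.depth_right = data.depth.copy()
        return out
    raise ValueError(f"unknown viewing condition {cond!r}")


# --------------------------------------------------------------------------
# Experiment matrix
# --------------------------------------------------------------------------


@dataclass
class ExperimentResults:
    per_image: pd.DataFrame        # one row per (cell, test image)
    per_object: pd.DataFrame       # one row per (cell, class)
    summary: pd.DataFrame          # one row per cell


def _cell_id(train_cond: str, test_cond: str) -> str:
    return f"{train_cond}:{test_cond}"


def validate_cell(train_cond: str, test_cond: str,
                  want_depth_metrics: bool = False) -> None:
    if train_cond not in VARIANT_FOR_TRAIN:
        raise ValueError(f"unknown training condition {train_cond!r}")
    if test_cond not in VIEWING_CONDITIONS:
        raise ValueError(f"unknown test condition {test_cond!r}")
    variant = VARIANT_FOR_TRAIN[train_cond]
    if variant == "monocular_unet" and test_cond != "standard":
        raise ValueError("the monocular U-net is tested on single images "
                         "(standard presentation only)")
    if want_depth_metrics and variant in ("binocular_seg_only",
                                          "monocular_unet"):
        raise ValueError(f"{train_cond} has no depth branch; depth metrics "
                         "are unavailable")


def train_for_condition(train_cond: TrainCondition,
                        train_data: training.FrameArrays,
                        val_data: training.FrameArrays,
                        net_cfg: network.NetworkConfig,
                        train_cfg: training.TrainConfig,
                        seed: int = 0,
                        runs_dir=None) -> network.ModelHandle:
    """Build and train (or load a cached) model for one training condition."""
    variant = VARIANT_FOR_TRAIN[train_cond]
    net_cfg = dataclasses.replace(net_cfg, variant=variant)
    model = network.build_network(net_cfg, seed=seed)
    ckpt = None
    if runs_dir is not None:
        ckpt = Path(runs_dir) / f"weights_{train_cond}_s{seed}.npz"
        if ckpt.exists():
            log.info("loading cached %s", ckpt)
            network.load_weights(model, ckpt)
            return model
    if train_cond == "identical_trained":
        train_data = condition_arrays(train_data, "identical")
        val_data = condition_arrays(val_data, "identical")
    cfg = dataclasses.replace(train_cfg, seed=seed)
    model, history = training.train_network(model, train_data, val_data, cfg)
    if ckpt is not None:
        ckpt.parent.mkdir(parents=True, exist_ok=True)
        network.save_weights(model, ckpt)
        history.to_csv(Path(runs_dir) / f"history_{train_cond}_s{seed}.csv")
    return model


def run_cell(model: network.ModelHandle, test_data: training.FrameArrays,
             train_cond: str, test_cond: str, batch: int = 4
             ) -> tuple[list[dict], list[pd.DataFrame]]:
    """Score one matrix cell; returns per-image metric dicts + rates tables."""
    validate_cell(train_cond, test_cond)
    variant = VARIANT_FOR_TRAIN[train_cond]
    data = condition_arrays(test_data, test_cond)
    has_depth = variant in ("binocular_full", "binocular_no_lateral")
    cfg = model.config
    rows, rates_list = [], []
    n = len(data)
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        if variant == "monocular_unet":
            preds = network.forward_pass(model, data.left[sl])
        else:
            preds = network.forward_pass(model, data.left[sl], data.right[sl])
        pred_labels = preds.left_seg_probs.argmax(axis=-1)
        for i in range(pred_labels.shape[0]):
            kw = {}
            if has_depth:
                kw["pred_depth"] = preds.depth_map[i]
                kw["truth_depth"] = data.depth[sl][i]
            res = evaluation.evaluate_frame(
                pred_labels[i], data.left_labels[sl][i], cfg.class_count, **kw)
            rates_list.append(res.pop("rates"))
            res["image"] = start + i
            rows.append(res)
    return rows, rates_list


def run_experiment_matrix(matrix_config: dict, data_manifest,
                          runs_dir=None, seed: int = 0,
                          test_split: str | None = "test"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train every required variant and score every requested cell.

    ``matrix_config`` keys: ``network`` (NetworkConfig fields), ``training``
    (TrainConfig fields), ``cells`` (list of [train_condition,
    test_condition]; defaults to the full standard matrix).  All cells are
    scored on the identical test frames, so per-image and per-object values
    are paired across cells.  Returns (per_image, summary); the per-object
    d' table is attached as ``summary.attrs['per_object']``.
    """
    cells = [tuple(c) for c in matrix_config.get("cells", DEFAULT_MATRIX)]
    for tc, vc in cells:
        validate_cell(tc, vc)
    if not cells:
        empty = pd.DataFrame()
        return empty, empty
    net_cfg = network.NetworkConfig(**matrix_config.get("network", {}))
    train_cfg = training.TrainConfig(**matrix_config.get("training", {}))

    train_data = training.FrameArrays.from_manifest(data_manifest, "train")
    val_data = training.FrameArrays.from_manifest(data_manifest, "val")
    test_data = training.FrameArrays.from_manifest(data_manifest, test_split)

    models: dict[str, network.ModelHandle] = {}
    rows = []
    object_rows = []
    for train_cond, test_cond in cells:
        if train_cond not in models:
            log.info("training condition %s (seed %d)", train_cond, seed)
            models[train_cond] = train_for_condition(
                train_cond, train_data, val_data, net_cfg, train_cfg,
                seed=seed, runs_dir=runs_dir)
        cell = _cell_id(train_cond, test_cond)
        log.info("scoring cell %s", cell)
        cell_rows, rates = run_cell(models[train_cond], test_data,
                                    train_cond, test_cond)
        for r in cell_rows:
            r.update(cell=cell, train_condition=train_cond,
                     test_condition=test_cond,
                     variant=VARIANT_FOR_TRAIN[train_cond])
            rows.append(r)
        table = evaluation.per_object_dprime_table(rates)
        table = table.reset_index()
        table.insert(0, "cell", cell)
        object_rows.append(table)
    per_image = pd.DataFrame(rows)
    per_object = pd.concat(object_rows, ignore_index=True)
    summary = summarize_cells(per_image, per_object)
    summary.attrs["per_object"] = per_object
    return per_image, summary


def summarize_cells(per_image: pd.DataFrame,
                    per_object: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per experiment cell: means and SDs of the per-image metrics."""
    if per_image.empty:
        return pd.DataFrame()
    agg = {"pixel_accuracy": ["mean", "std"], "mean_dprime": ["mean", "std"]}
    if "depth_rmse" in per_image:
        agg["depth_rmse"] = ["mean", "std"]
        agg["depth_mean_error"] = ["mean"]
    g = per_image.groupby(["cell", "train_condition", "test_condition"],
                          sort=False).agg(agg)
    g.columns = ["_".join(c).removesuffix("_mean") for c in g.columns]
    g = g.reset_index()
    if per_object is not None and not per_object.empty:
        obj = (per_object[~per_object["missing"]]
               .groupby("cell", sort=False)["mean_dprime"].mean()
               .rename("mean_object_dprime"))
        g = g.merge(obj, on="cell", how="left")
    return g


def paired_cells(per_image: pd.DataFrame, metric: str, cell_a: str,
                 cell_b: str, family_size: int = 1
                 ) -> evaluation.PairedComparison:
    """Related-samples comparison of a per-image metric between two cells."""
    a = per_image.query("cell == @cell_a").sort_values("image")[metric]
    b = per_image.query("cell == @cell_b").sort_values("image")[metric]
    return evaluation.paired_comparison(a.to_numpy(), b.to_numpy(),
                                        family_size=family_size)


# --------------------------------------------------------------------------
# Reduced-scale ordering study
# --------------------------------------------------------------------------

#: Study conditions for a desk-scale replication of the condition
#: comparisons: a small scene family, 48x48 stereo frames, a narrow network
#: and a short training schedule.  The qualitative predictions under test —
#: standard presentation beats pseudoscopic presentation on both depth RMSE
#: and segmentation d' — do not depend on full-scale training.
SCALED_STUDY = {
    "scene": dict(n_objects=6, category_count=6, floor_radius=2.5,
                  object_size_range=(0.5, 1.0)),
    "rig": dict(baseline=0.065, focal_length_px=96,
                image_width=32, image_height=32),
    "plan": dict(train=8, val=2, test=2, frames_per_scene=10,
                 test_frames_per_scene=20),
    "network": dict(input_height=32, input_width=32, class_count=7,
                    encoder_depth=2, seg_widths=(8, 16, 32),
                    depth_widths=(8, 16, 32)),
    "training": dict(max_epochs=60, batch_size=8, steps_per_epoch=12,
                     early_stop_patience=55),
    "cells": [["standard", "standard"], ["standard", "swapped"],
              ["no_lateral", "standard"]],
}


def run_scaled_study(seed: int, workdir, n_seeds: int = 3) -> pd.DataFrame:
    """Run the reduced-scale standard-vs-pseudoscopic study.

    For each of ``n_seeds`` independent replicates (fresh dataset, fresh
    weights), trains the full binocular model and its no-lateral twin, then
    scores standard and swapped presentation on the same test images.
    Returns one row per (replicate, cell) with mean depth RMSE and mean
    per-object d'.
    """
    from .scene_synth import CameraRig, SceneSpec, SplitPlan, generate_dataset

    workdir = Path(workdir)
    rows = []
    for rep in range(n_seeds):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        data_dir = workdir / f"rep{rep}"
        spec = SceneSpec(**SCALED_STUDY["scene"])
        rig = CameraRig(**SCALED_STUDY["rig"])
        plan = SplitPlan(**SCALED_STUDY["plan"])
        generate_dataset(spec, rig, plan, data_dir, seed=rep_seed,
                         overwrite=True)
        cfg = {k: SCALED_STUDY[k] for k in ("network", "training", "cells")}
        per_image, summary = run_experiment_matrix(cfg, data_dir,
                                                   seed=rep_seed)
        for _, r in summary.iterrows():
            rows.append({
                "replicate": rep, "seed": rep_seed, "cell": r["cell"],
                "depth_rmse": r.get("depth_rmse"),
                "mean_object_dprime": r.get("mean_object_dprime"),
            })
        log.info("replicate %d done", rep)
    return pd.DataFrame(rows)


def ordering_outcomes(study: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate orderings from a run_scaled_study table."""
    out = []
    for rep, g in study.groupby("replicate"):
        g = g.set_index("cell")
        std = g.loc["standard:standard"]
        swp = g.loc["standard:swapped"]
        row = {
            "replicate": rep,
            "rmse_standard": std["depth_rmse"],
            "rmse_swapped": swp["depth_rmse"],
            "dprime_standard": std["mean_object_dprime"],
            "dprime_swapped": swp["mean_object_dprime"],
            "rmse_ordering_ok": std["depth_rmse"] < swp["depth_rmse"],
            "dprime_ordering_ok": (std["mean_object_dprime"]
                                   > swp["mean_object_dprime"]),
        }
        if "no_lateral:standard" in g.index:
            row["rmse_no_lateral"] = g.loc["no_lateral:standard", "depth_rmse"]
        out.append(row)
    return pd.DataFrame(out)


def paired_object_dprime(per_object: pd.DataFrame, cell_a: str, cell_b: str,
                         family_size: int = 1) -> evaluation.PairedComparison:
    """Paired test on per-object mean d' between two cells (df = classes-1)."""
    a = per_object.query("cell == @cell_a").set_index("class_id")["mean_dprime"]
    b = per_object.query("cell == @cell_b").set_index("class_id")["mean_dprime"]
    idx = a.index.intersection(b.index)
    return evaluation.paired_comparison(a.loc[idx].to_numpy(),
                                        b.loc[idx].to_numpy(),
                                        family_size=family_size)
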