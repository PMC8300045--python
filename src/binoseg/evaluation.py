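"""Depth-error and signal-detection segmentation metrics, plus the paired
statistical comparisons used to contrast viewing conditions.

Segmentation is scored per object class with signal-detection theory:

* hit rate — fraction of the class's true pixels predicted as that class;
* object false-alarm rate — fraction of non-target pixels *belonging to
  other objects* (background excluded from the pool) predicted as the
  class; a deliberately conservative false-alarm definition;
* d' = z(hit) - z(fa), with rates clamped to [1/(2N), 1 - 1/(2N)] using
  each rate's own denominator N (the standard log-linear-style correction
  for perfect scores), so d' is always finite.

The background class is scored as a 25th category; its "object" false-alarm
pool is all object pixels.  Depth is scored as the per-pixel signed error
(estimate - truth, in normalized depth units) and its per-image RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scene_synth import BACKGROUND_ID


# --------------------------------------------------------------------------
# Depth metrics
# --------------------------------------------------------------------------


@dataclass
class DepthErrorStats:
    error_map: np.ndarray         # estimate - truth, normalized depth units
    mean_signed: float
    sd_signed: float
    rmse: float


def depth_error_stats(pred_depth: np.ndarray, truth_depth: np.ndarray
                      ) -> DepthErrorStats:
    """Signed per-pixel depth error (estimate - truth) and its summaries."""
    pred = np.asarray(pred_depth, dtype=np.float64)
    if pred.ndim == 3 and pred.shape[-1] == 1:
        pred = pred[..., 0]
    truth = np.asarray(truth_depth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    err = pred - truth
    return DepthErrorStats(
        error_map=err,
        mean_signed=float(err.mean()),
        sd_signed=float(err.std()),
        rmse=float(np.sqrt((err ** 2).mean())),
    )


# --------------------------------------------------------------------------
# Segmentation confusion and rates
# --------------------------------------------------------------------------


def segmentation_confusion(pred_labels: np.ndarray, truth_labels: np.ndarray,
                           class_count: int) -> pd.DataFrame:
    """Per-class confusion counts from a pair of label maps.

    ``class_count`` counts all classes including background (id 0).
    Columns: true_pixels, correct, pred_total, pred_from_background,
    pred_from_other_objects, plus ``pixel_accuracy`` as a DataFrame attr.
    """
    pred = np.asarray(pred_labels).ravel()
    truth = np.asarray(truth_labels).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label map shapes differ")
    for name, a in (("pred", pred), ("truth", truth)):
        if a.min() < 0 or a.max() >= class_count:
            raise ValueError(f"{name} labels outside 0..{class_count - 1}")
    conf = np.bincount(truth * class_count + pred,
                       minlength=class_count * class_count
                       ).reshape(class_count, class_count)
    true_pixels = conf.sum(axis=1)
    pred_total = conf.sum(axis=0)
    correct = np.diag(conf)
    pred_from_bg = conf[BACKGROUND_ID, :].copy()
    object_rows = conf[1:, :]
    pred_from_other = object_rows.sum(axis=0) - np.where(
        np.arange(class_count) >= 1, correct, 0)
    # for the background class, every object pixel is a potential false alarm
    df = pd.DataFrame({
        "true_pixels": true_pixels,
        "correct": correct,
        "pred_total": pred_total,
        "pred_from_background": pred_from_bg,
        "pred_from_other_objects": pred_from_other,
    })
    df.index.name = "class_id"
    df.attrs["pixel_accuracy"] = float(correct.sum() / max(truth.size, 1))
    return df


def detection_rates(confusion: pd.DataFrame) -> pd.DataFrame:
    """Hit and object-false-alarm rates (and their denominators) per class.

    Classes with an empty denominator get NaN and present=False; they are
    excluded from per-object averages downstream.
    """
    class_count = len(confusion)
    true_pixels = confusion["true_pixels"].to_numpy()
    object_pixels = true_pixels[1:].sum()
    fa_pool = np.empty(class_count, dtype=np.int64)
    fa_pool[0] = object_pixels
    fa_pool[1:] = object_pixels - true_pixels[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        hit = confusion["correct"].to_numpy() / true_pixels
        fa = confusion["pred_from_other_objects"].to_numpy() / fa_pool
    df = pd.DataFrame({
        "hit_rate": np.where(true_pixels > 0, hit, np.nan),
        "fa_rate": np.where(fa_pool > 0, fa, np.nan),
        "n_true": true_pixels,
        "n_fa_pool": fa_pool,
    })
    df["present"] = (df["n_true"] > 0) & (df["n_fa_pool"] > 0)
    df.index.name = "class_id"
    return df


# --------------------------------------------------------------------------
# d-prime
# --------------------------------------------------------------------------


def dprime_from_rates(hit, fa, clamp_n_hit, clamp_n_fa):
    """d' = z(hit) - z(fa) with 1/(2N) boundary clamping.

    ``clamp_n_hit`` / ``clamp_n_fa`` are the denominators behind each rate;
    rates are clamped into [1/(2N), 1 - 1/(2N)] before the normal quantile
    so perfect scores stay finite.  Vectorizes over array inputs.
    """
    hit = np.asarray(hit, dtype=np.float64)
    fa = np.asarray(fa, dtype=np.float64)
    n_h = np.asarray(clamp_n_hit, dtype=np.float64)
    n_f = np.asarray(clamp_n_fa, dtype=np.float64)
    if (n_h < 1).any() or (n_f < 1).any():
        raise ValueError("clamp counts must be >= 1")
    if ((hit < 0) | (hit > 1) | (fa < 0) | (fa > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    h = np.clip(hit, 1.0 / (2 * n_h), 1.0 - 1.0 / (2 * n_h))
    f = np.clip(fa, 1.0 / (2 * n_f), 1.0 - 1.0 / (2 * n_f))
    d = stats.norm.ppf(h) - stats.norm.ppf(f)
    return float(d) if d.ndim == 0 else d


def image_dprimes(rates: pd.DataFrame) -> pd.Series:
    """Per-class d' for one image; NaN for classes not scoreable there."""
    out = np.full(len(rates), np.nan)
    m = rates["present"].to_numpy()
    if m.any():
        out[m] = dprime_from_rates(
            rates.loc[m, "hit_rate"], rates.loc[m, "fa_rate"],
            rates.loc[m, "n_true"], rates.loc[m, "n_fa_pool"])
    return pd.Series(out, index=rates.index, name="dprime")


def per_object_dprime_table(per_image_rates: list[pd.DataFrame]
                            ) -> pd.DataFrame:
    """Mean and SD of per-image d' for every class (objects + background).

    d' is computed per class *per image*, skipping images where the class
    is absent, then averaged across images — giving one row per class so
    that paired tests across conditions have df = class_count - 1.
    """
    if not per_image_rates:
        raise ValueError("no per-image rates supplied")
    d = pd.concat([image_dprimes(r) for r in per_image_rates], axis=1)
    table = pd.DataFrame({
        "mean_dprime": d.mean(axis=1, skipna=True),
        "sd_dprime": d.std(axis=1, ddof=1),
        "n_images": d.notna().sum(axis=1),
    })
    table["missing"] = table["n_images"] == 0
    table.index.name = "class_id"
    return table


# --------------------------------------------------------------------------
# Paired statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    t: float
    df: int
    p: float                  # two-tailed
    p_adjusted: float         # Bonferroni, capped at 1
    cohen_d: float
    family_size: int
    n: int


def paired_comparison(values_a, values_b, family_size: int = 1
                      ) -> PairedComparison:
    """Related-samples t-test with Bonferroni adjustment and paired Cohen's d.

    t = mean(diff) / (SD(diff) / sqrt(n)) with SD using n-1 degrees of
    freedom; d = mean(diff) / SD(diff).  All-zero differences give the
    degenerate t = 0, p = 1 result; zero-variance differences with nonzero
    mean are an error (no meaningful paired test exists).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(t=0.0, df=n - 1, p=1.0, p_adjusted=1.0,
                                    cohen_d=0.0, family_size=family_size, n=n)
        raise ValueError("zero-variance differences with nonzero mean")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparison(
        t=float(t), df=n - 1, p=float(p),
        p_adjusted=float(min(1.0, family_size * p)),
        cohen_d=float(mean / sd), family_size=family_size, n=n)


# --------------------------------------------------------------------------
# Frame-level evaluation and directory scoring
# --------------------------------------------------------------------------


def evaluate_frame(pred_labels: np.ndarray, truth_labels: np.ndarray,
                   class_count: int,
                   pred_depth: np.ndarray | None = None,
                   truth_depth: np.ndarray | None = None) -> dict:
    """All metrics for one test image: accuracy, rates table, depth stats."""
    conf = segmentation_confusion(pred_labels, truth_labels, class_count)
    rates = detection_rates(conf)
    out = {
        "pixel_accuracy": conf.attrs["pixel_accuracy"],
        "rates": rates,
        "mean_hit_rate": float(rates.loc[rates["present"], "hit_rate"].mean()),
        "mean_fa_rate": float(rates.loc[rates["present"], "fa_rate"].mean()),
        "mean_dprime": float(image_dprimes(rates).mean(skipna=True)),
    }
    if pred_depth is not None and truth_depth is not None:
        d = depth_error_stats(pred_depth, truth_depth)
        out.update(depth_mean_error=d.mean_signed, depth_sd_error=d.sd_signed,
                   depth_rmse=d.rmse)
    return out


def evaluate_directories(pred_dir, truth_dir, class_count: int = 25
                         ) -> pd.DataFrame:
    """Score saved predictions against ground truth, one row per frame.

    Both directories hold frame subdirectories with ``left_labels.png``
    (and optionally ``depth_left.png``) as written by the dataset/prediction
    writers.
    """
    import imageio.v3 as iio

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    rows = []
    frames = sorted(p.parent.relative_to(pred_dir)
                    for p in pred_dir.rglob("left_labels.png"))
    if not frames:
        raise FileNotFoundError(f"no predictions under {pred_dir}")
    for rel in frames:
        pl = iio.imread(pred_dir / rel / "left_labels.png").astype(np.int64)
        tl = iio.imread(truth_dir / rel / "left_labels.png").astype(np.int64)
        pd_path = pred_dir / rel / "depth_left.png"
        td_path = truth_dir / rel / "depth_left.png"
        kw = {}
        if pd_path.exists() and td_path.exists():
            kw["pred_depth"] = iio.imread(pd_path).astype(np.float64) / 65535.0
            kw["truth_depth"] = iio.imread(td_path).astype(np.float64) / 65535.0
        res = evaluate_frame(pl, tl, class_count, **kw)
        row = {"frame": str(rel)}
        row.update({k: v for k, v in res.items() if k != "rates"})
        rows.append(row)
    return pd.DataFrame(rows)
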