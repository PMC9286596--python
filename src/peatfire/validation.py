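"""Map validation against hotspot-density observations.

A probability map is binarized at a threshold (default 0.75) and compared
pixelwise with an observed-fire mask derived from the yearly hotspot
density map (default: at or above the year's 90th density percentile).
Metrics are confusion-matrix proportions times 100. Undefined ratios
(zero denominators) stay None rather than being coerced to 0 or 100 —
low-fire years would otherwise distort every summary they enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError
from .hotspots import DensityMap
from .model import ModelVariant, TrainingTable, predict_map, train


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ValidationMetrics:
    accuracy: float | None
    precision: float | None
    recall: float | None
    prob_threshold: float
    density_threshold: float
    year: int | None = None


def binarize_prediction(prob: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Positive iff probability >= threshold (inclusive); NaN propagates."""
    if not 0 <= threshold <= 1:
        raise ValueError("probability threshold must be within [0, 1]")
    prob = np.asarray(prob, dtype=float)
    out = np.where(np.isfinite(prob), (prob >= threshold).astype(float), np.nan)
    return out


def density_threshold(density: DensityMap, percentile: float = 90.0,
                      ) -> tuple[float, np.ndarray]:
    """The year's density threshold and the observed-fire mask.

    The threshold is the given percentile of the per-pixel density
    distribution, zeros included. The mask uses an inclusive >= rule,
    except when the threshold is 0 (a near-zero-fire year), where strict >
    avoids declaring the entire map burnt.
    """
    vals = np.asarray(density.values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("density map holds no evaluable pixels")
    # order statistic (no interpolation): the smallest observed density
    # with at least the stated fraction of pixels at or below it
    thr = float(np.percentile(finite, percentile, method="higher"))
    if thr > 0:
        mask = vals >= thr
    else:
        mask = vals > thr
    obs = np.where(np.isfinite(vals), mask.astype(float), np.nan)
    return thr, obs


def confusion(pred: np.ndarray, obs: np.ndarray) -> ConfusionMatrix:
    """Pixel counts over the mutually valid footprint of two boolean maps."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise AlignmentError("prediction and observation grids differ")
    valid = np.isfinite(pred) & np.isfinite(obs)
    p = pred[valid] > 0.5
    o = obs[valid] > 0.5
    return ConfusionMatrix(
        tp=int(np.sum(p & o)), tn=int(np.sum(~p & ~o)),
        fp=int(np.sum(p & ~o)), fn=int(np.sum(~p & o)))


def metrics(cm: ConfusionMatrix, prob_threshold: float = 0.75,
            density_thr: float = 0.0, year: int | None = None,
            ) -> ValidationMetrics:
    """Accuracy, precision, recall as percentages; None where undefined."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    prec = 100.0 * cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    rec = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    return ValidationMetrics(accuracy=acc, precision=prec, recall=rec,
                             prob_threshold=prob_threshold,
                             density_threshold=density_thr, year=year)


def evaluate(prob: np.ndarray, density: DensityMap,
             prob_thr: float = 0.75, density_percentile: float = 90.0,
             bounds_mask: np.ndarray | None = None) -> ValidationMetrics:
    """One-call evaluation at the standard thresholds."""
    dthr, obs = density_threshold(density, density_percentile)
    pred = binarize_prediction(prob, prob_thr)
    if bounds_mask is not None:
        pred = np.where(bounds_mask, pred, np.nan)
        obs = np.where(bounds_mask, obs, np.nan)
    return metrics(confusion(pred, obs), prob_thr, dthr, density.year)


def threshold_sweep(prob: np.ndarray, density: DensityMap,
                    prob_thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
                    density_thresholds=tuple(float(t) for t in range(1, 11)),
                    bounds_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Metrics over a grid of probability x absolute-density thresholds.

    Density thresholds are in hotspots/km^2 (compared inclusively), the
    axis used to map out the validation space of an individual year.
    Returns one row per threshold pair.
    """
    prob_thresholds = sorted(prob_thresholds)
    density_thresholds = sorted(density_thresholds)
    if not prob_thresholds or not density_thresholds:
        raise ValueError("threshold ranges must be non-empty")
    vals = density.values
    rows = []
    for dthr in density_thresholds:
        obs = np.where(np.isfinite(vals), (vals >= dthr).astype(float), np.nan)
        for pthr in prob_thresholds:
            pred = binarize_prediction(prob, pthr)
            if bounds_mask is not None:
                pred = np.where(bounds_mask, pred, np.nan)
                obs_m = np.where(bounds_mask, obs, np.nan)
            else:
                obs_m = obs
            cm = confusion(pred, obs_m)
            m = metrics(cm, pthr, dthr, density.year)
            rows.append({
                "year": density.year, "prob_threshold": pthr,
                "density_threshold": dthr, "TP": cm.tp, "TN": cm.tn,
                "FP": cm.fp, "FN": cm.fn, "accuracy": m.accuracy,
                "precision": m.precision, "recall": m.recall,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leave-one-year-out
# ---------------------------------------------------------------------------

@dataclass
class LoyoResult:
    per_year: pd.DataFrame
    summary: dict[str, dict]
    trained_years: dict[int, tuple[int, ...]] = field(default_factory=dict)


def _summarize(series: pd.Series) -> dict:
    vals = series.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        return {"median": None, "q1": None, "q3": None, "iqr": None,
                "outliers": []}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [float(v) for v in vals if v < lo or v > hi]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "iqr": float(iqr), "outliers": outliers}


def leave_one_year_out(tables_by_year: dict[int, TrainingTable],
                       stacks_by_year: dict,
                       density_by_year: dict[int, DensityMap],
                       variant: ModelVariant,
                       param_grid: dict[str, list],
                       split_seed: int = 0,
                       prob_threshold: float = 0.75,
                       density_percentile: float = 90.0,
                       bounds_mask: np.ndarray | None = None) -> LoyoResult:
    """Temporal cross-validation: evaluate each year with a model trained
    on all the others.

    A held-out year whose table is empty or single-class still gets a row
    (its model is trained on the remaining years regardless); metrics that
    are undefined for it stay None instead of the year being dropped.
    """
    years = sorted(tables_by_year)
    if len(years) < 3:
        raise ValueError("leave-one-year-out needs at least 3 years")
    rows = []
    trained_years: dict[int, tuple[int, ...]] = {}
    for held in years:
        train_years = tuple(y for y in years if y != held)
        frames = [tables_by_year[y].frame for y in train_years
                  if len(tables_by_year[y].frame)]
        merged = pd.concat(frames, ignore_index=True)
        table = TrainingTable(frame=merged,
                              feature_names=tables_by_year[held].feature_names)
        fitted = train(table, param_grid=param_grid, split_seed=split_seed,
                       variant=variant)
        trained_years[held] = train_years
        prob = predict_map(fitted, stacks_by_year[held])
        m = evaluate(prob, density_by_year[held], prob_threshold,
                     density_percentile, bounds_mask)
        rows.append({"year": held, "accuracy": m.accuracy,
                     "precision": m.precision, "recall": m.recall,
                     "density_threshold": m.density_threshold})
    per_year = pd.DataFrame(rows)
    summary = {metric: _summarize(per_year[metric])
               for metric in ("accuracy", "precision", "recall")}
    return LoyoResult(per_year=per_year, summary=summary,
                      trained_years=trained_years)
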