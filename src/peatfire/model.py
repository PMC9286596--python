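"""Gradient-boosted fire-susceptibility models.

Three model variants differ only in which seasonal layers they see:
``M_pre`` uses pre-fire-season (May-Jul) means plus the August-minus-
pre-season deltas, ``M_fire`` uses fire-season (Aug-Oct) means, and
``M_pre_and_fire`` the union. All variants share the static layers
(distances, land cover, clearance index, ONI, terrain, peat depth,
drought indices). Training is a 70:30 stratified split with exhaustive
grid search over hyper-parameters scored by held-out log-loss, then a
refit of the winning combination on the full table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split

from .exceptions import AlignmentError
from .features import SeasonalFeatureStack
from .hotspots import TrainingPoint

VARIANT_NAMES = ("M_pre_and_fire", "M_fire", "M_pre")

DEFAULT_PARAM_GRID: dict[str, list] = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [100, 300],
    "subsample": [0.8, 1.0],
}

#: feature -> driver-group mapping used for grouped importance reporting
def group_for_feature(name: str) -> str:
    if name.startswith("dist_"):
        return "anthropogenic_proximity"
    if name.startswith("lc_") or name == "clearance_index":
        return "land_cover"
    if name.split("_")[0] in ("ndvi", "evi", "etpet"):
        return "vegetation_indices"
    return "environmental"  # elevation, slope, aspect, peat depth, ONI, SPEI


@dataclass(frozen=True)
class ModelVariant:
    name: str
    layer_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}")


def make_variant(name: str, all_layers: list[str]) -> ModelVariant:
    """Select the layer subset for a variant from an available layer set.

    Seasonal layers are recognised by suffix: ``*_pre`` (pre-season mean),
    ``*_fire`` (fire-season mean), ``*_delta`` (Aug minus pre-season);
    everything else is shared by all variants.
    """
    pre = [n for n in all_layers if n.endswith("_pre")]
    fire = [n for n in all_layers if n.endswith("_fire")]
    delta = [n for n in all_layers if n.endswith("_delta")]
    shared = [n for n in all_layers if n not in pre + fire + delta]
    chosen = {
        "M_pre": shared + pre + delta,
        "M_fire": shared + fire,
        "M_pre_and_fire": shared + pre + fire + delta,
    }[name]
    return ModelVariant(name=name, layer_names=tuple(sorted(chosen)))


@dataclass
class TrainingTable:
    """Rows of (year, x, y, features..., label) harvested at sample points."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...]
    n_dropped: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()


@dataclass
class FittedModel:
    variant: ModelVariant
    booster: xgb.XGBClassifier
    chosen_params: dict
    split_seed: int
    gain_importance: dict[str, float]  # proportions summing to 1

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.booster.predict_proba(X[list(self.variant.layer_names)])[:, 1]


@dataclass
class ImportanceReport:
    per_feature: dict[str, float]
    per_group: dict[str, float]
    top10: list[tuple[str, float]]


# ---------------------------------------------------------------------------

def assemble_table(points: list[TrainingPoint],
                   stacks: dict[int, SeasonalFeatureStack],
                   variant: ModelVariant) -> TrainingTable:
    """Sample every variant layer at each training point's cell.

    Rows with any non-finite feature are dropped (and counted), so the
    table satisfies the no-missing-values contract of the booster input.
    """
    rows = []
    for pt in points:
        if pt.year not in stacks:
            raise AlignmentError(f"no feature stack for year {pt.year}")
        stack = stacks[pt.year]
        missing = [n for n in variant.layer_names if n not in stack.layers]
        if missing:
            raise AlignmentError(
                f"stack for year {pt.year} lacks layers {missing}")
        r, c = stack.grid.point_to_rowcol(pt.x, pt.y)
        if not (0 <= r < stack.grid.n_rows and 0 <= c < stack.grid.n_cols):
            continue
        feats = {n: float(stack.layers[n][r, c]) for n in variant.layer_names}
        rows.append({"year": pt.year, "x": pt.x, "y": pt.y,
                     "label": pt.label, **feats})
    frame = pd.DataFrame(rows)
    n_before = len(frame)
    if n_before:
        frame = frame.dropna().reset_index(drop=True)
    return TrainingTable(frame=frame, feature_names=variant.layer_names,
                         n_dropped=n_before - len(frame),
                         provenance={"n_points": len(points)})


def _make_classifier(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        tree_method="hist", n_jobs=1, random_state=seed,
        eval_metric="logloss", **params)


def train(table: TrainingTable, param_grid: dict[str, list] | None = None,
          split_seed: int = 0, variant: ModelVariant | None = None) -> FittedModel:
    """Grid-search hyper-parameters on a 70:30 stratified split, refit best.

    Every combination in ``param_grid`` is fitted on the 70% portion and
    scored by log-loss on the held-out 30%; the best (ties broken by grid
    order) is refitted on the full table. Deterministic given the seeds
    and single-threaded histogram construction.
    """
    param_grid = param_grid or DEFAULT_PARAM_GRID
    if variant is None:
        variant = ModelVariant(name="M_pre_and_fire",
                               layer_names=table.feature_names)
    # canonical row order: the fit depends on row content only, never on
    # the order rows were assembled in
    frame = table.frame.sort_values(
        ["year", "x", "y", "label"], kind="mergesort").reset_index(drop=True)
    y = frame["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    X = frame[list(table.feature_names)]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, stratify=y, random_state=split_seed)

    keys = sorted(param_grid)
    best_score, best_params = np.inf, None
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        clf = _make_classifier(params, split_seed)
        clf.fit(X_tr, y_tr)
        score = log_loss(y_te, clf.predict_proba(X_te)[:, 1], labels=[0, 1])
        if score < best_score:
            best_score, best_params = score, params

    final = _make_classifier(best_params, split_seed)
    final.fit(X, y)

    raw = final.get_booster().get_score(importance_type="gain")
    gains = {n: raw.get(n, 0.0) for n in variant.layer_names}
    total = sum(gains.values())
    if total > 0:
        gains = {n: g / total for n, g in gains.items()}
    return FittedModel(variant=variant, booster=final, chosen_params=best_params,
                       split_seed=split_seed, gain_importance=gains)


def predict_map(model: FittedModel, stack: SeasonalFeatureStack) -> np.ndarray:
    """Per-pixel fire probability; NaN wherever any input layer is NaN."""
    names = list(model.variant.layer_names)
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise AlignmentError(f"stack lacks layers {missing}")
    flat = np.column_stack([stack.layers[n].ravel() for n in names])
    valid = np.isfinite(flat).all(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        X = pd.DataFrame(flat[valid], columns=names)
        out[valid] = model.booster.predict_proba(X)[:, 1]
    return out.reshape(stack.grid.shape)


def importance_report(model: FittedModel,
                      grouping: dict[str, str] | None = None) -> ImportanceReport:
    """Proportional gain importances, their 4-group aggregation, and top 10.

    Groups follow the driver taxonomy: environmental (terrain, peat depth,
    ONI, drought indices), anthropogenic proximity (distances), vegetation
    indices, and land cover (classes plus clearance index).
    """
    feats = model.variant.layer_names
    if grouping is None:
        grouping = {n: group_for_feature(n) for n in feats}
    missing = [n for n in feats if n not in grouping]
    if missing:
        raise KeyError(f"features {missing} missing from grouping")
    per_feature = dict(model.gain_importance)
    per_group: dict[str, float] = {}
    for n, v in per_feature.items():
        per_group[grouping[n]] = per_group.get(grouping[n], 0.0) + v
    top10 = sorted(per_feature.items(), key=lambda kv: -kv[1])[:10]
    return ImportanceReport(per_feature=per_feature, per_group=per_group,
                            top10=top10)
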