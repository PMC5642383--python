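"""Random-forest regression feature selection for regional mutation density.

The procedure regresses per-window mutation counts on chromatin features
with a bootstrap ensemble of regression trees and evaluates everything on
out-of-bag (OOB) data:

* **OOB variance explained** — the pseudo-R² ``1 − MSE_oob / Var(y)``, where
  each window's OOB prediction averages the trees whose bootstrap sample did
  not contain it.  No held-out test set is needed.
* **Permutation importance** — for each tree and feature, the feature's
  values are permuted *within that tree's OOB rows* and the per-tree OOB MSE
  increase (permuted − untouched) is averaged over trees.
* **Greedy backward elimination** — restrict to the top-k features by
  importance, then repeatedly refit, record the OOB variance explained, and
  drop the currently least-important feature until one remains.  The VE
  recorded at the step where a feature is the weakest member of the active
  set is that feature's selection score.
* **Repeat aggregation** — the whole cycle is repeated with independent
  sub-seeds; per-feature scores are summarised (mean/min/max) and a feature
  is *significant* when its mean elimination-step VE reaches the full-model
  mean VE minus one standard error of that mean (and is positive).

Trees are sklearn ``DecisionTreeRegressor``s; the bootstrap, OOB and
importance bookkeeping is implemented here because per-tree OOB permutation
differences are not exposed by stock forest implementations.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from . import _seeds
from .features import FeatureMatrix
from .quantify import DensityVector

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMS = {
    # regression-forest convention: F/3 candidate features per split
    "max_features": "third",
    "min_samples_leaf": 5,
}


def _resolve_xy(X, y) -> tuple[np.ndarray, list[str], np.ndarray]:
    if isinstance(X, FeatureMatrix):
        arr, names = X.X, X.names
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D")
        names = [f"f{i}" for i in range(arr.shape[1])]
    yv = y.values if isinstance(y, DensityVector) else np.asarray(y, dtype=float)
    if len(yv) != arr.shape[0]:
        raise ValueError("X and y have different numbers of windows")
    return arr, names, yv


def _max_features(spec, F: int) -> int:
    if spec in ("third", None):
        return max(1, F // 3)
    if isinstance(spec, float):
        return max(1, int(spec * F))
    return min(int(spec), F)


@dataclass
class ForestModel:
    trees: list[DecisionTreeRegressor]
    oob_masks: np.ndarray            # n_trees × W boolean
    oob_predictions: np.ndarray      # per-window mean over OOB trees
    feature_names: list[str]
    n_trees: int
    seed: int
    hyperparams: dict = field(default_factory=dict)


def fit_forest(
    X,
    y,
    n_trees: int = 1000,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> ForestModel:
    """Fit a bootstrap regression forest with per-tree OOB bookkeeping.

    Each tree trains on W draws with replacement; the windows not drawn are
    that tree's OOB set.  The bootstrap is re-drawn (with a fresh sub-seed)
    in the unlikely event that some window is in-bag for every tree, so OOB
    predictions are defined everywhere.  Deterministic for a fixed seed.
    """
    arr, names, yv = _resolve_xy(X, y)
    W, F = arr.shape
    if W <= 10:
        raise ValueError("need more than 10 windows to fit a forest")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    mf = _max_features(hp["max_features"], F)

    const = np.ptp(arr, axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant feature column(s): {[names[i] for i in np.where(const)[0]]}",
            stacklevel=2,
        )

    for attempt in itertools.count():
        boots = [
            _seeds.bootstrap_rng(seed, t, attempt).integers(0, W, size=W)
            for t in range(n_trees)
        ]
        oob_masks = np.ones((n_trees, W), dtype=bool)
        for t, idx in enumerate(boots):
            oob_masks[t, idx] = False
        if oob_masks.any(axis=0).all():
            break
        logger.warning("bootstrap redraw %d: some window had no OOB tree", attempt + 1)

    trees = []
    pred_sum = np.zeros(W)
    pred_cnt = np.zeros(W)
    for t, idx in enumerate(boots):
        tree = DecisionTreeRegressor(
            max_features=mf,
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=_seeds.tree_seed(seed, t),
        )
        tree.fit(arr[idx], yv[idx])
        oob = oob_masks[t]
        if oob.any():
            pred_sum[oob] += tree.predict(arr[oob])
            pred_cnt[oob] += 1
        trees.append(tree)
    oob_predictions = pred_sum / pred_cnt
    return ForestModel(trees, oob_masks, oob_predictions, names, n_trees, seed,
                       {**hp, "max_features_resolved": mf})


def oob_variance_explained(model: ForestModel, y) -> float:
    """OOB pseudo-R²: 1 − mean((y − oob_pred)²) / Var(y).  May be negative."""
    yv = y.values if isinstance(y, DensityVector) else np.asarray(y, dtype=float)
    var = float(np.var(yv))
    if var == 0.0:
        warnings.warn("Var(y) = 0; variance explained defined as 0", stacklevel=2)
        return 0.0
    mse = float(np.mean((yv - model.oob_predictions) ** 2))
    return 1.0 - mse / var


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # feature, importance, rank (1 = most important)

    def __post_init__(self) -> None:
        ranks = sorted(self.table["rank"])
        if ranks != list(range(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..F")

    def top(self, k: int) -> list[str]:
        t = self.table.sort_values("rank")
        return t["feature"].head(k).tolist()

    def lowest(self) -> str:
        return self.table.loc[self.table["rank"].idxmax(), "feature"]


def _rank_importances(names: Sequence[str], imps: np.ndarray) -> ImportanceTable:
    order = sorted(range(len(names)), key=lambda i: (-imps[i], names[i]))
    rank = np.empty(len(names), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return ImportanceTable(
        pd.DataFrame({"feature": list(names), "importance": imps, "rank": rank})
    )


def permutation_importance(
    model: ForestModel, X, y, seed: int | None = None
) -> ImportanceTable:
    """Per-tree OOB permutation importance.

    For tree *t* and feature *m*: permute column *m* within the tree's OOB
    rows (sub-stream ``(PERMUTE, t, m)`` of ``seed``), and take the OOB MSE
    difference (permuted − untouched).  A feature's raw importance is the
    mean difference over trees; ranks are by descending importance with ties
    broken lexicographically by feature name.
    """
    arr, names, yv = _resolve_xy(X, y)
    if names != model.feature_names and len(names) == len(model.feature_names):
        names = model.feature_names
    if seed is None:
        seed = model.seed
    F = arr.shape[1]
    imps = np.zeros(F)
    for t, tree in enumerate(model.trees):
        oob = model.oob_masks[t]
        n = int(oob.sum())
        if n == 0:
            continue
        Xo = arr[oob]
        yo = yv[oob]
        base_mse = np.mean((yo - tree.predict(Xo)) ** 2)
        # stack all F permuted variants so each tree predicts once
        big = np.tile(Xo, (F, 1))
        for m in range(F):
            perm = _seeds.permutation_rng(seed, t, m).permutation(n)
            big[m * n:(m + 1) * n, m] = Xo[perm, m]
        preds = tree.predict(big).reshape(F, n)
        imps += np.mean((yo[None, :] - preds) ** 2, axis=1) - base_mse
    imps /= model.n_trees
    return _rank_importances(names, imps)


@dataclass
class EliminationPath:
    steps: list[tuple[tuple[str, ...], float]]  # (active features, VE) per step
    feature_step_ve: dict[str, float]           # VE at each feature's removal step
    removed_order: list[str]                    # first-removed … last-surviving

    @property
    def final_feature(self) -> str:
        return self.removed_order[-1]


def backward_elimination(
    X,
    y,
    importance: ImportanceTable,
    keep: int = 20,
    n_trees: int = 100,
    seed: int = 0,
    hyperparams: dict | None = None,
    rerank: bool = True,
) -> EliminationPath:
    """Greedy backward elimination from the top-``keep`` features down to one.

    Starting from the ``keep`` highest-ranked features, iteratively refit the
    forest on the active set, record its OOB variance explained, and remove
    the currently least-important member.  With ``rerank=True`` (default)
    importances are recomputed at every step; ``rerank=False`` freezes the
    initial ranking.  Each feature's selection score is the VE of the step
    at which it was the weakest active feature.
    """
    arr, names, yv = _resolve_xy(X, y)
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if keep > len(names):
        raise ValueError(f"keep={keep} exceeds number of features ({len(names)})")
    col = {nm: j for j, nm in enumerate(names)}
    active = importance.top(keep)
    frozen_rank = {r.feature: r.rank for r in importance.table.itertuples()}

    steps: list[tuple[tuple[str, ...], float]] = []
    feature_step_ve: dict[str, float] = {}
    removed: list[str] = []
    for step in range(keep):
        sub = arr[:, [col[nm] for nm in active]]
        sub_seed = _seeds.elimination_seed(seed, step)
        model = fit_forest(sub, yv, n_trees=n_trees, seed=sub_seed,
                           hyperparams=hyperparams)
        model.feature_names = list(active)
        ve = oob_variance_explained(model, yv)
        steps.append((tuple(active), ve))
        if len(active) == 1:
            feature_step_ve[active[0]] = ve
            removed.append(active[0])
            break
        if rerank:
            imp = permutation_importance(model, sub, yv, seed=sub_seed)
            imp.table["feature"] = list(active)
            worst = imp.lowest()
        else:
            worst = max(active, key=lambda nm: (frozen_rank[nm], nm))
        feature_step_ve[worst] = ve
        removed.append(worst)
        active = [nm for nm in active if nm != worst]
    return EliminationPath(steps, feature_step_ve, removed)


@dataclass
class SelectionSummary:
    per_feature: pd.DataFrame
    full_model_ve: float
    sem: float
    threshold: float
    significant_features: list[str]
    n_repeats: int
    repeat_full_ve: np.ndarray
    repeat_top_sets: list[frozenset]

    def to_json(self, path=None) -> str:
        payload = {
            "full_model_ve": self.full_model_ve,
            "sem": self.sem,
            "threshold": self.threshold,
            "significant_features": self.significant_features,
            "n_repeats": self.n_repeats,
            "per_feature": self.per_feature.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def run_selection(
    X,
    y,
    n_trees: int = 1000,
    n_repeats: int = 1000,
    keep: int = 20,
    seed: int = 0,
    hyperparams: dict | None = None,
    rerank: bool = True,
) -> SelectionSummary:
    """Repeat fit → importance → elimination with independent sub-seeds and
    aggregate.

    Per feature: mean raw importance across repeats, and the mean/min/max of
    its elimination-step VE over the repeats in which it reached the top-k
    set.  The significance line is the mean full-model VE minus one standard
    error of that mean across repeats; a feature is significant when its mean
    step VE reaches the line and is positive.
    """
    arr, names, yv = _resolve_xy(X, y)
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (SEM undefined otherwise)")
    F = len(names)
    imp_acc = np.zeros(F)
    step_ve: dict[str, list[float]] = {nm: [] for nm in names}
    full_ves = np.empty(n_repeats)
    top_sets: list[frozenset] = []
    for r in range(n_repeats):
        rs = _seeds.repeat_seed(seed, r)
        model = fit_forest(arr, yv, n_trees=n_trees, seed=rs, hyperparams=hyperparams)
        model.feature_names = list(names)
        full_ves[r] = oob_variance_explained(model, yv)
        imp = permutation_importance(model, arr, yv, seed=rs)
        imp.table["feature"] = list(names)
        imp_acc += imp.table.set_index("feature").loc[names, "importance"].to_numpy()
        path = backward_elimination(
            X, y, imp, keep=min(keep, F), n_trees=n_trees, seed=rs,
            hyperparams=hyperparams, rerank=rerank,
        )
        top_sets.append(frozenset(path.feature_step_ve))
        for nm, ve in path.feature_step_ve.items():
            step_ve[nm].append(ve)

    mean_imp = imp_acc / n_repeats
    full_mean = float(np.mean(full_ves))
    sem = float(np.std(full_ves, ddof=1) / np.sqrt(n_repeats))
    threshold = full_mean - sem
    rank_tab = _rank_importances(names, mean_imp)
    rank_map = {r.feature: r.rank for r in rank_tab.table.itertuples()}
    rows = []
    for nm in names:
        ves = step_ve[nm]
        rows.append(
            {
                "feature": nm,
                "mean_importance": mean_imp[names.index(nm)],
                "importance_rank": rank_map[nm],
                "n_in_top": len(ves),
                "step_ve_mean": float(np.mean(ves)) if ves else float("nan"),
                "step_ve_min": float(np.min(ves)) if ves else float("nan"),
                "step_ve_max": float(np.max(ves)) if ves else float("nan"),
            }
        )
    per_feature = pd.DataFrame(rows).sort_values("importance_rank").reset_index(drop=True)
    significant = [
        row["feature"]
        for _, row in per_feature.iterrows()
        if row["n_in_top"] > 0
        and row["step_ve_mean"] >= threshold
        and row["step_ve_mean"] > 0
    ]
    return SelectionSummary(
        per_feature, full_mean, sem, threshold, significant,
        n_repeats, full_ves, top_sets,
    )
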