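"""Differential-chromatin region selection and mutation-frequency prediction.

Given two aligned per-window signal tracks for the same mark in two tissues
(a "source" tissue the cells are thought to have shifted toward, and the
"target" tissue of origin), select the windows where the target tissue has
excess signal — top residuals of the target~source regression plus a
target > source direction constraint — and then ask which tissue's signal
better predicts the observed mutation frequency in those windows: fit one
linear model of mutation density on each tissue's track (on all windows),
predict both at the selected windows, and compare predictions with the
observations by a paired two-sided location test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import DensityVector


@dataclass
class LinearModel:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_ols(x, y) -> tuple[LinearModel, np.ndarray]:
    """Ordinary least squares y ~ x; returns the model and residuals."""
    x = np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, DensityVector) else np.asarray(y, dtype=float)
    if len(x) != len(yv):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("Var(x) = 0: regression undefined")
    res = stats.linregress(x, yv)
    model = LinearModel(float(res.slope), float(res.intercept),
                        float(res.rvalue ** 2), len(x))
    residuals = yv - model.predict(x)
    return model, residuals


@dataclass
class RegionSelection:
    indices: np.ndarray        # selected window indices, ascending
    residuals: np.ndarray      # per-window residuals (full length)
    signal_diff: np.ndarray    # target − source at the selected windows
    top_fraction: float
    n_candidates: int          # top-residual windows before the direction rule

    def __len__(self) -> int:
        return len(self.indices)


def select_differential_regions(
    signal_target,
    signal_source,
    top_fraction: float = 0.05,
) -> RegionSelection:
    """Windows where the target tissue shows excess signal over the source.

    Regress target on source over all windows; rank windows by residual
    (descending, ties broken by window index); keep the top
    ``ceil(top_fraction · W)`` windows, then retain only those where the
    target signal exceeds the source signal.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    tgt = np.asarray(signal_target, dtype=float)
    src = np.asarray(signal_source, dtype=float)
    if len(tgt) != len(src):
        raise ValueError("signal tracks must be aligned")
    _, residuals = fit_ols(src, tgt)
    W = len(tgt)
    k = math.ceil(top_fraction * W)
    order = sorted(range(W), key=lambda i: (-residuals[i], i))
    candidates = order[:k]
    selected = sorted(i for i in candidates if tgt[i] > src[i])
    idx = np.asarray(selected, dtype=int)
    return RegionSelection(idx, residuals, tgt[idx] - src[idx],
                           top_fraction, len(candidates))


@dataclass
class PredictionComparison:
    observed: np.ndarray
    predicted_a: np.ndarray
    predicted_b: np.ndarray
    model_a: LinearModel
    model_b: LinearModel
    tests: dict[str, dict[str, float]]  # obs_vs_a / obs_vs_b / a_vs_b


def _paired_test(u: np.ndarray, v: np.ndarray, method: str) -> dict[str, float]:
    d = u - v
    if method == "wilcoxon":
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(u, v, alternative="two-sided")
    elif method == "ttest":
        if np.ptp(d) == 0:
            stat, p = (0.0, 1.0) if d[0] == 0 else (math.inf, 0.0)
        else:
            stat, p = stats.ttest_rel(u, v)
    else:
        raise ValueError(f"unknown test {method!r}")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_difference": float(np.median(d)),
    }


def predict_and_compare(
    y_train,
    x_a,
    x_b,
    selection: RegionSelection,
    test: str = "wilcoxon",
) -> PredictionComparison:
    """Compare two single-track linear predictions of mutation frequency.

    Both models are trained on all windows (observed density vs one tissue's
    track each) and evaluated at the selected windows; observed-vs-predicted
    and predicted-vs-predicted differences are tested with a paired
    two-sided Wilcoxon signed-rank test (paired t-test via ``test="ttest"``).
    """
    if len(selection) == 0:
        raise ValueError("empty region selection")
    yv = y_train.values if isinstance(y_train, DensityVector) else np.asarray(
        y_train, dtype=float)
    xa = np.asarray(x_a, dtype=float)
    xb = np.asarray(x_b, dtype=float)
    model_a, _ = fit_ols(xa, yv)
    model_b, _ = fit_ols(xb, yv)
    idx = selection.indices
    obs = yv[idx]
    pa = model_a.predict(xa[idx])
    pb = model_b.predict(xb[idx])
    tests = {
        "obs_vs_a": _paired_test(obs, pa, test),
        "obs_vs_b": _paired_test(obs, pb, test),
        "a_vs_b": _paired_test(pa, pb, test),
    }
    return PredictionComparison(obs, pa, pb, model_a, model_b, tests)


def accuracy_vs_difference(
    selection: RegionSelection,
    comparison: PredictionComparison,
) -> tuple[pd.DataFrame, float]:
    """Per-region chromatin difference vs prediction error for model *a*.

    Returns a table (window index, target − source signal difference,
    |observed − predicted_a|) and the Spearman correlation between the two
    columns.  Larger-difference regions predicting better shows up as a
    negative correlation.  With tied/constant columns the correlation is
    undefined and reported as NaN with a warning.
    """
    diff = selection.signal_diff
    err = np.abs(comparison.observed - comparison.predicted_a)
    table = pd.DataFrame(
        {"window_index": selection.indices, "signal_difference": diff,
         "abs_error_a": err}
    )
    if np.ptp(diff) == 0 or np.ptp(err) == 0:
        warnings.warn("correlation undefined for constant column; reporting NaN",
                      stacklevel=2)
        return table, float("nan")
    rho, _ = stats.spearmanr(diff, err)
    return table, float(rho)
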