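"""Variance explained by tissue/cell-type feature categories.

Chromatin features are grouped by the tissue or cell type they were measured
in (each category sharing a common panel of marks, e.g. H3K27me3, H3K36me3,
H3K4me1, H3K4me3, H3K9me3 ± accessibility).  For each category the forest is
fitted on that category's columns alone and its OOB variance explained is
compared against a null distribution built from repeated random draws of
equally many features from the full (optionally category-excluded) pool.
The empirical p-value uses the add-one permutation estimator, so it is never
exactly zero and its resolution floor is 1/(n_iter + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seeds
from .features import FeatureMatrix
from .forest import fit_forest, oob_variance_explained
from .quantify import correlate_feature


@dataclass
class FeatureCategory:
    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"category {self.name!r} has no members")


def categories_from_matrix(X: FeatureMatrix) -> list[FeatureCategory]:
    """One category per distinct track ``category`` annotation."""
    groups: dict[str, list[str]] = {}
    for t in X.tracks:
        groups.setdefault(t.category, []).append(t.name)
    return [FeatureCategory(name, members) for name, members in groups.items()]


@dataclass
class CategoryVE:
    category: str
    ve_mean: float
    ve_min: float
    ve_max: float
    repeat_ves: np.ndarray


def category_ve(
    X: FeatureMatrix,
    y,
    cat: FeatureCategory,
    n_trees: int = 100,
    n_repeats: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> CategoryVE:
    """OOB variance explained using only the category's features."""
    missing = set(cat.members) - set(X.names)
    if missing:
        raise KeyError(f"category {cat.name!r} members absent from matrix: "
                       f"{sorted(missing)}")
    sub = X.subset(cat.members)
    ves = np.empty(n_repeats)
    for r in range(n_repeats):
        rs = _seeds.repeat_seed(seed, r)
        model = fit_forest(sub, y, n_trees=n_trees, seed=rs, hyperparams=hyperparams)
        ves[r] = oob_variance_explained(model, y)
    return CategoryVE(cat.name, float(ves.mean()), float(ves.min()),
                      float(ves.max()), ves)


@dataclass
class NullResult:
    null_distribution: np.ndarray
    subset_size: int
    n_iter: int
    observed_ve: float | None = None
    empirical_p: float | None = None
    subsets: list[tuple[str, ...]] = field(default_factory=list)


def empirical_p_value(null: np.ndarray, observed: float) -> float:
    """Add-one estimator: (1 + #{null ≥ observed}) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    return float((1 + int((null >= observed).sum())) / (1 + len(null)))


def random_subset_null(
    X_pool: FeatureMatrix,
    y,
    subset_size: int = 6,
    n_iter: int = 1000,
    exclude: FeatureCategory | None = None,
    seed: int = 0,
    n_trees: int = 100,
    hyperparams: dict | None = None,
    observed_ve: float | None = None,
) -> NullResult:
    """VE null distribution from random same-size feature subsets.

    Each iteration draws ``subset_size`` features without replacement from
    the pool (minus ``exclude``'s members, if given), fits the forest on
    them, and records the OOB variance explained.  If ``observed_ve`` is
    given, the add-one empirical p-value of the observation is attached.
    """
    pool = list(X_pool.names)
    if exclude is not None:
        excluded = set(exclude.members)
        pool = [nm for nm in pool if nm not in excluded]
    if subset_size > len(pool):
        raise ValueError(f"subset_size={subset_size} exceeds pool size {len(pool)}")
    nulls = np.empty(n_iter)
    subsets = []
    for it in range(n_iter):
        draw_rng = _seeds.rng(seed, _seeds.SUBSET, it)
        picked = [pool[j] for j in draw_rng.choice(len(pool), subset_size,
                                                   replace=False)]
        subsets.append(tuple(picked))
        model = fit_forest(X_pool.subset(picked), y, n_trees=n_trees,
                           seed=_seeds.repeat_seed(seed, it),
                           hyperparams=hyperparams)
        nulls[it] = oob_variance_explained(model, y)
    p = empirical_p_value(nulls, observed_ve) if observed_ve is not None else None
    return NullResult(nulls, subset_size, n_iter, observed_ve, p, subsets)


def category_correlation(
    X: FeatureMatrix,
    cat_a: FeatureCategory,
    cat_b: FeatureCategory,
    method: str = "spearman",
) -> float:
    """Correlation between two categories' assay-matched signal profiles.

    The two categories must carry the same multiset of assays; their tracks
    are ordered by assay name, concatenated across windows, and correlated
    (Spearman by default).
    """
    def _assay_sorted(cat):
        tracks = [X.track(nm) for nm in cat.members]
        assays = sorted(t.assay for t in tracks)
        return assays, sorted(tracks, key=lambda t: (t.assay, t.name))

    assays_a, tracks_a = _assay_sorted(cat_a)
    assays_b, tracks_b = _assay_sorted(cat_b)
    if assays_a != assays_b:
        raise ValueError(
            f"assay mismatch between categories {cat_a.name!r} ({assays_a}) "
            f"and {cat_b.name!r} ({assays_b})"
        )
    va = np.concatenate([t.values for t in tracks_a])
    vb = np.concatenate([t.values for t in tracks_b])
    return correlate_feature(va, vb, method=method)


@dataclass
class CategoryResult:
    category: str
    ve_mean: float
    ve_min: float
    ve_max: float
    empirical_p: float
    reference_ve: float
    null_distribution: np.ndarray


def partition_categories(
    X: FeatureMatrix,
    y,
    categories: list[FeatureCategory],
    reference_ve: float,
    subset_size: int = 6,
    n_iter: int = 1000,
    n_trees: int = 100,
    n_repeats: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Per-category VE with random-subset null p-values, as one table.

    ``exclude_self=True`` removes each category's own members from the null
    pool (the stricter comparison); otherwise all features are eligible.
    The shared null (when ``exclude_self`` is off) is computed once.
    """
    rows = []
    shared_null = None
    if not exclude_self:
        shared_null = random_subset_null(
            X, y, subset_size=subset_size, n_iter=n_iter, seed=seed,
            n_trees=n_trees, hyperparams=hyperparams,
        )
    for k, cat in enumerate(categories):
        cv = category_ve(X, y, cat, n_trees=n_trees, n_repeats=n_repeats,
                         seed=_seeds.derive_int(seed, 7, k),
                         hyperparams=hyperparams)
        null = shared_null if shared_null is not None else random_subset_null(
            X, y, subset_size=subset_size, n_iter=n_iter, exclude=cat,
            seed=_seeds.derive_int(seed, 8, k), n_trees=n_trees,
            hyperparams=hyperparams,
        )
        p = empirical_p_value(null.null_distribution, cv.ve_mean)
        rows.append(
            {
                "category": cat.name,
                "n_members": len(cat.members),
                "ve_mean": cv.ve_mean,
                "ve_min": cv.ve_min,
                "ve_max": cv.ve_max,
                "empirical_p": p,
                "reference_ve": reference_ve,
                "null_q95": float(np.quantile(null.null_distribution, 0.95)),
                "null_q99": float(np.quantile(null.null_distribution, 0.99)),
            }
        )
    return pd.DataFrame(rows)
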