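"""Principal coordinate analysis of regional mutation profiles.

Samples are compared by the correlation of their per-window mutation count
vectors; the dissimilarity between two samples is 1 − Pearson r (range
[0, 2]).  Classical (metric) scaling then embeds the samples: square the
dissimilarities, Gower double-center, eigendecompose, and scale the top-k
eigenvectors by the square roots of their (clamped-at-zero) eigenvalues.
1 − r dissimilarities need not be Euclidean, so negative eigenvalues can
occur; they are clamped and their relative mass reported, never silently
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .quantify import DensityVector

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    sample_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_labels)
        if v.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        self.values = v


@dataclass
class PCOAResult:
    coordinates: np.ndarray       # n × k
    eigenvalues: np.ndarray       # k, nonincreasing (pre-clamp values)
    negative_eigenvalue_mass: float
    sample_labels: list[str]

    def to_tsv(self, coords_path, eigvals_path=None) -> None:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"PCo{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample_id", self.sample_labels)
        df.to_csv(coords_path, sep="\t", index=False)
        if eigvals_path is not None:
            pd.DataFrame(
                {"axis": np.arange(1, k + 1), "eigenvalue": self.eigenvalues}
            ).to_csv(eigvals_path, sep="\t", index=False)


def dissimilarity(
    profiles: list[DensityVector] | np.ndarray,
    sample_labels: list[str] | None = None,
    normalize: bool = False,
) -> DissimilarityMatrix:
    """1 − Pearson correlation between every pair of per-window profiles.

    ``normalize=True`` divides each profile by its total count first (the
    Pearson correlation is not invariant to per-sample totals only when
    profiles are subsequently combined; provided for completeness).
    """
    if isinstance(profiles, np.ndarray):
        mat = np.asarray(profiles, dtype=float)
        labels = sample_labels or [f"s{i}" for i in range(mat.shape[0])]
    else:
        mat = np.vstack([p.values for p in profiles])
        labels = sample_labels or [
            p.group_label or f"s{i}" for i, p in enumerate(profiles)
        ]
    for i, row in enumerate(mat):
        if np.ptp(row) == 0:
            raise ValueError(f"profile {labels[i]!r} is constant; "
                             "correlation undefined")
    if normalize:
        mat = mat / mat.sum(axis=1, keepdims=True)
    r = np.corrcoef(mat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    # enforce the mathematical range [0, 2]; perfectly (anti)correlated
    # profiles land exactly on the endpoints despite rounding
    d = np.clip(d, 0.0, 2.0)
    d[np.abs(d) < 1e-12] = 0.0
    d[np.abs(d - 2.0) < 1e-12] = 2.0
    return DissimilarityMatrix(d, labels)


def embed(D: DissimilarityMatrix, k: int = 2) -> PCOAResult:
    """Classical scaling of a dissimilarity matrix into k dimensions."""
    n = len(D.sample_labels)
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples ({n})")
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total_abs = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total_abs) if total_abs else 0.0
    if neg_mass > 0:
        logger.info("PCoA: negative eigenvalue mass %.3g (non-Euclidean "
                    "dissimilarities); negative eigenvalues clamped to 0", neg_mass)
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(np.clip(lam, 0.0, None))
    # reproducible axis orientation: largest-|loading| entry positive
    for j in range(k):
        col = coords[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return PCOAResult(coords, lam, neg_mass, list(D.sample_labels))


def plot_embedding(result: PCOAResult, color_by: dict[str, str] | None = None,
                   path=None, ax=None):
    """Scatter plot of the first two coordinates, optionally colored by a
    per-sample label (e.g. cohort or IGHV status)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = [
        (color_by or {}).get(s, "sample") for s in result.sample_labels
    ]
    for lab in sorted(set(labels)):
        mask = np.array([l == lab for l in labels])
        ax.scatter(result.coordinates[mask, 0], result.coordinates[mask, 1],
                   label=lab, s=25)
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
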