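"""Per-window quantification of mutations and chromatin signal.

Turns mutation catalogs and scored interval tracks into vectors aligned to a
WindowSet, aggregates samples into groups (regional mutation density of a
cohort is the sum over its samples), partitions paired precancer/cancer
samples into private and shared mutation sets, and computes rank/linear
correlations between densities and chromatin tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationCatalog
from .features import FeatureTrack
from .windows import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class DensityVector:
    """Per-window mutation counts for a sample group, aligned to a WindowSet."""

    values: np.ndarray
    group_label: str = ""
    n_samples: int = 1
    n_dropped: int = 0  # records falling in no retained window

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("density values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"window_index": np.arange(len(self.values)), "count": self.values}
        ).to_csv(path, sep="\t", index=False)


def count_mutations_per_window(
    cat: MutationCatalog,
    ws: WindowSet,
    sample_ids: Iterable[str] | None = None,
    group_label: str = "",
) -> DensityVector:
    """Count mutations per window for the given samples.

    Mutations outside every retained window are dropped and the drop count
    recorded, so that sum(values) + n_dropped equals the number of selected
    records.
    """
    if sample_ids is None:
        ids = set(cat.metadata.index)
        rec = cat.records
    else:
        ids = set(sample_ids)
        unknown = ids - set(cat.metadata.index)
        if unknown:
            raise KeyError(f"unknown sample_id(s): {sorted(unknown)}")
        rec = cat.records[cat.records["sample_id"].isin(ids)]
    values = np.zeros(len(ws), dtype=float)
    n_dropped = 0
    if len(rec):
        idx = ws.locate(rec["chrom"].to_numpy(), rec["pos"].to_numpy())
        n_dropped = int((idx < 0).sum())
        np.add.at(values, idx[idx >= 0], 1.0)
        if n_dropped:
            logger.info("count_mutations_per_window: %d/%d records outside "
                        "retained windows", n_dropped, len(rec))
    return DensityVector(values, group_label=group_label, n_samples=len(ids),
                         n_dropped=n_dropped)


def aggregate_group(
    cat: MutationCatalog,
    ws: WindowSet,
    group_filter: Callable[[pd.Series], bool],
    group_label: str = "",
) -> DensityVector:
    """Summed per-window counts over the samples selected by ``group_filter``.

    ``group_filter`` receives one metadata row (a Series) per sample and
    must return True for samples to include.  Selecting zero samples is an
    error.
    """
    ids = cat.select_samples(group_filter)
    if not ids:
        raise ValueError("group_filter selected no samples")
    return count_mutations_per_window(cat, ws, ids, group_label=group_label)


def signal_per_window(
    intervals: pd.DataFrame,
    ws: WindowSet,
    mode: str = "read_count",
) -> np.ndarray:
    """Aggregate scored intervals (chrom, start, end[, score]) per window.

    ``read_count``: each interval is assigned to the single window containing
    its midpoint (one read, one window — no double counting).
    ``score_sum``: each interval contributes score × (overlap length /
    interval length) to every window it overlaps, so the total assigned
    signal is conserved over retained windows.
    """
    if mode not in ("read_count", "score_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    values = np.zeros(len(ws), dtype=float)
    if not len(intervals):
        return values
    starts = intervals["start"].to_numpy(np.int64)
    ends = intervals["end"].to_numpy(np.int64)
    if (ends <= starts).any():
        raise ValueError("intervals must have positive length")
    chroms = intervals["chrom"].to_numpy()
    if mode == "read_count":
        mid = (starts + ends) // 2
        idx = ws.locate(chroms, mid)
        np.add.at(values, idx[idx >= 0], 1.0)
        return values
    scores = intervals["score"].to_numpy(float)
    if (scores < 0).any():
        raise ValueError("score_sum requires nonnegative scores")
    size = ws.window_size
    lengths = (ends - starts).astype(float)
    # distribute each interval over the consecutive window-aligned slots it
    # spans, then map slots to retained windows
    for c, s, e, sc, ln in zip(chroms, starts, ends, scores, lengths):
        first = (s // size) * size
        w = np.arange(first, e, size)
        overlap = np.minimum(e, w + size) - np.maximum(s, w)
        idx = ws.locate(np.repeat(c, len(w)), w)
        keep = idx >= 0
        values[idx[keep]] += sc * overlap[keep] / ln
    return values


def partition_paired_mutations(
    cat: MutationCatalog,
    pair_id: str,
    precancer_cohort: str = "precancer",
) -> tuple[MutationCatalog, MutationCatalog, MutationCatalog]:
    """Split a matched precancer/cancer pair into private and shared calls.

    Mutation identity is (chrom, pos, ref, alt); sample of origin is ignored
    for matching.  Returns (precancer-only, common, cancer-only) catalogs —
    three disjoint sets whose union is the pair's distinct mutations.  The
    precancer member of the pair is the sample whose cohort label equals
    ``precancer_cohort``.
    """
    meta = cat.metadata
    members = meta.index[meta["pair_id"] == pair_id].tolist()
    if len(members) != 2:
        raise ValueError(
            f"pair {pair_id!r} has {len(members)} samples; expected exactly 2"
        )
    pre = [s for s in members if meta.loc[s, "cohort"] == precancer_cohort]
    if len(pre) != 1:
        raise ValueError(
            f"pair {pair_id!r}: expected exactly one sample with cohort "
            f"{precancer_cohort!r}, found {len(pre)}"
        )
    pre_id = pre[0]
    can_id = [s for s in members if s != pre_id][0]

    key_cols = ["chrom", "pos", "ref", "alt"]
    rec = cat.records
    pre_rec = rec[rec["sample_id"] == pre_id].drop_duplicates(subset=key_cols)
    can_rec = rec[rec["sample_id"] == can_id].drop_duplicates(subset=key_cols)
    pre_keys = set(map(tuple, pre_rec[key_cols].itertuples(index=False)))
    can_keys = set(map(tuple, can_rec[key_cols].itertuples(index=False)))
    common_keys = pre_keys & can_keys

    def _pick(df, keys, keep):
        mask = [
            (t in keys) == keep
            for t in df[key_cols].itertuples(index=False, name=None)
        ]
        return df[np.asarray(mask, dtype=bool)] if len(df) else df

    meta_pair = meta.loc[members].reset_index()
    pre_only = MutationCatalog(_pick(pre_rec, common_keys, False), meta_pair)
    common = MutationCatalog(_pick(pre_rec, common_keys, True), meta_pair)
    can_only = MutationCatalog(_pick(can_rec, common_keys, False), meta_pair)
    return pre_only, common, can_only


def correlate_feature(
    density: DensityVector | np.ndarray,
    track: FeatureTrack | np.ndarray,
    method: str = "spearman",
) -> float:
    """Rank (Spearman) or linear (Pearson) correlation over windows."""
    x = density.values if isinstance(density, DensityVector) else np.asarray(density, float)
    y = track.values if isinstance(track, FeatureTrack) else np.asarray(track, float)
    if len(x) != len(y):
        raise ValueError("density and track lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 windows to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        r, _ = stats.spearmanr(x, y)
    elif method == "pearson":
        r, _ = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)
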