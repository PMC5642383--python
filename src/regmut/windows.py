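"""Fixed-width genomic window frames.

The coordinate frame for every downstream computation is a tiling of each
(auto)chromosome into equal-width windows (1 Mbp by default elsewhere).
Windows are 0-based half-open, aligned to multiples of the window size, and
the trailing partial window of each chromosome is dropped so that all windows
have identical width and densities are directly comparable.

Windows can be removed by any-overlap against exclusion regions (centromeres,
telomeres, blacklists, differentially-methylated regions) and by a mappable-
coverage fraction threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)


class GenomeWindow(NamedTuple):
    chrom: str
    start: int
    end: int
    index: int


def _chrom_sort_key(chrom: str):
    m = _AUTOSOME_RE.match(chrom)
    if m:
        return (0, int(m.group(2)), chrom)
    return (1, 0, chrom)


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


@dataclass
class RegionList:
    """A plain list of (chrom, start, end) regions, 0-based half-open."""

    df: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"RegionList requires columns {sorted(required)}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("RegionList: every record must have start < end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]], label: str = ""
    ) -> "RegionList":
        df = pd.DataFrame(list(records), columns=["chrom", "start", "end"])
        return cls(df, label=label)

    @classmethod
    def from_bed(cls, path, label: str = "") -> "RegionList":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
            dtype={"chrom": str},
        )
        return cls(df, label=label or str(path))

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class WindowSet:
    """Ordered, equal-width, non-overlapping genomic windows.

    ``df`` holds columns chrom/start/end/index sorted by (chrom, start) with
    genome-wide consecutive indices 0..n-1.
    """

    df: pd.DataFrame
    window_size: int
    genome_label: str = ""
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if len(df):
            widths = df["end"] - df["start"]
            if not (widths == self.window_size).all():
                raise ValueError("all windows must have width == window_size")
            if not (df["start"] % self.window_size == 0).all():
                raise ValueError("window starts must be multiples of window_size")
            order = sorted(
                range(len(df)),
                key=lambda i: _chrom_sort_key(df["chrom"].iat[i]) + (df["start"].iat[i],),
            )
            df = df.iloc[order].reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "start"])
            if dup.any():
                raise ValueError("overlapping/duplicate windows")
        df["index"] = np.arange(len(df), dtype=int)
        self.df = df
        # per-chrom sorted start arrays + genome-wide index arrays for lookups
        self._by_chrom = {
            chrom: (
                sub["start"].to_numpy(),
                sub["index"].to_numpy(),
            )
            for chrom, sub in df.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomeWindow(row.chrom, int(row.start), int(row.end), int(row.index))

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def locate(self, chrom: np.ndarray | Sequence[str], pos: np.ndarray) -> np.ndarray:
        """Map positions to window indices; -1 where no retained window covers."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for c in np.unique(chrom):
            entry = self._by_chrom.get(c)
            if entry is None:
                continue
            starts, gidx = entry
            mask = chrom == c
            cand = (pos[mask] // self.window_size) * self.window_size
            j = np.searchsorted(starts, cand)
            ok = (j < len(starts)) & (starts[np.clip(j, 0, len(starts) - 1)] == cand)
            vals = np.full(mask.sum(), -1, dtype=np.int64)
            vals[ok] = gidx[j[ok]]
            out[mask] = vals
        return out

    def overlap_hits(self, regions: RegionList) -> np.ndarray:
        """Boolean mask over windows: True where the window overlaps ≥1 region by ≥1 bp."""
        hit = np.zeros(len(self), dtype=bool)
        size = self.window_size
        for c, sub in regions.df.groupby("chrom", sort=False):
            entry = self._by_chrom.get(c)
            if entry is None:
                continue
            starts, gidx = entry
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                # window [w, w+size) overlaps [s, e) iff s - size < w < e
                lo = np.searchsorted(starts, s - size, side="right")
                hi = np.searchsorted(starts, e, side="left")
                hit[gidx[lo:hi]] = True
        return hit

    def coverage_fraction(self, regions: RegionList) -> np.ndarray:
        """Fraction of each window covered by the (merged) regions."""
        cov = np.zeros(len(self), dtype=float)
        size = self.window_size
        for c, sub in regions.df.groupby("chrom", sort=False):
            entry = self._by_chrom.get(c)
            if entry is None:
                continue
            starts, gidx = entry
            for s, e in _merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            ):
                lo = np.searchsorted(starts, s - size, side="right")
                hi = np.searchsorted(starts, e, side="left")
                w = starts[lo:hi]
                overlap = np.minimum(e, w + size) - np.maximum(s, w)
                cov[gidx[lo:hi]] += overlap
        return cov / size

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end", "index"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path, window_size: int, genome_label: str = "") -> "WindowSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        return cls(df, window_size=window_size, genome_label=genome_label)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            yield cur_s, cur_e
            cur_s, cur_e = s, e
    if cur_s is not None:
        yield cur_s, cur_e


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) → ordered dict."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str}
    )
    return dict(zip(df["chrom"], df["length"].astype(int)))


def make_windows(
    chrom_sizes: Mapping[str, int],
    window_size: int,
    autosomes_only: bool = True,
    genome_label: str = "",
) -> WindowSet:
    """Tile each chromosome into ``window_size`` windows from position 0.

    Trailing partial windows are dropped.  Windows are ordered by
    (chromosome, start) with chromosomes in natural order, and assigned
    genome-wide consecutive indices.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has nonpositive length {length}")
    chroms = [
        c for c in chrom_sizes if (not autosomes_only or is_autosome(c))
    ]
    chroms.sort(key=_chrom_sort_key)
    rows = []
    for c in chroms:
        n = chrom_sizes[c] // window_size
        for i in range(n):
            rows.append((c, i * window_size, (i + 1) * window_size))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return WindowSet(df, window_size=window_size, genome_label=genome_label)


def filter_windows(
    ws: WindowSet,
    exclusions: RegionList | None = None,
    mappable: RegionList | None = None,
    min_mappable_frac: float = 0.5,
) -> WindowSet:
    """Drop windows touching exclusion regions or with poor mappable coverage.

    A window is removed if it overlaps any exclusion record by at least one
    base, or if the fraction of its bases covered by ``mappable`` records is
    below ``min_mappable_frac``.  ``mappable=None`` skips the coverage test.
    Surviving windows keep their coordinates; indices are re-assigned.
    """
    drop = np.zeros(len(ws), dtype=bool)
    if exclusions is not None and len(exclusions):
        drop |= ws.overlap_hits(exclusions)
    if mappable is not None:
        drop |= ws.coverage_fraction(mappable) < min_mappable_frac
    kept = ws.df.loc[~drop, ["chrom", "start", "end"]]
    logger.info(
        "filter_windows: %d/%d windows retained (min_mappable_frac=%s)",
        len(kept), len(ws), min_mappable_frac,
    )
    return WindowSet(kept, window_size=ws.window_size, genome_label=ws.genome_label)


def exclude_windows_overlapping(
    ws: WindowSet, regions: RegionList
) -> tuple[WindowSet, int]:
    """Remove every window overlapping ≥1 region by ≥1 bp.

    Returns the surviving WindowSet and the number of windows dropped.
    Used e.g. to remove megabase windows containing differentially
    methylated CpG regions before feature selection.
    """
    if not len(regions):
        return replace(ws, df=ws.df.copy()), 0
    hit = ws.overlap_hits(regions)
    kept = ws.df.loc[~hit, ["chrom", "start", "end"]]
    n_dropped = int(hit.sum())
    logger.info("exclude_windows_overlapping(%s): dropped %d windows",
                regions.label, n_dropped)
    return (
        WindowSet(kept, window_size=ws.window_size, genome_label=ws.genome_label),
        n_dropped,
    )
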