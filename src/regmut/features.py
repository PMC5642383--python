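"""Per-window chromatin feature tracks and the window × feature matrix.

Each track is one epigenomic assay (a histone-mark ChIP-seq read count,
a DNase I hypersensitivity peak score, a Repli-seq score, ...) summarised
per window, annotated with the tissue/cell-type it was measured in
(``category``) and the assay/mark name (``assay``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .windows import WindowSet


@dataclass
class FeatureTrack:
    name: str
    values: np.ndarray
    category: str = ""
    assay: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FeatureTrack values must be 1-D")


@dataclass
class FeatureMatrix:
    """Ordered collection of same-length FeatureTracks aligned to a WindowSet."""

    tracks: list[FeatureTrack]
    window_ref: WindowSet | None = None

    def __post_init__(self) -> None:
        lengths = {len(t.values) for t in self.tracks}
        if len(lengths) > 1:
            raise ValueError("all tracks must have the same length")
        names = [t.name for t in self.tracks]
        if len(set(names)) != len(names):
            raise ValueError("track names must be unique")
        if self.window_ref is not None and self.tracks:
            if len(self.tracks[0].values) != len(self.window_ref):
                raise ValueError("track length does not match window set")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def n_windows(self) -> int:
        return len(self.tracks[0].values) if self.tracks else 0

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tracks]

    @property
    def X(self) -> np.ndarray:
        """Window × feature value matrix."""
        return np.column_stack([t.values for t in self.tracks])

    def track(self, name: str) -> FeatureTrack:
        for t in self.tracks:
            if t.name == name:
                return t
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        by_name = {t.name: t for t in self.tracks}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return FeatureMatrix([by_name[n] for n in names], window_ref=self.window_ref)

    def restrict_windows(self, keep: np.ndarray) -> "FeatureMatrix":
        """Row-subset all tracks (boolean mask or index array over windows)."""
        tracks = [
            FeatureTrack(t.name, t.values[keep], t.category, t.assay)
            for t in self.tracks
        ]
        return FeatureMatrix(tracks, window_ref=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({t.name: t.values for t in self.tracks})

    def annotations(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [t.name for t in self.tracks],
                "category": [t.category for t in self.tracks],
                "assay": [t.assay for t in self.tracks],
            }
        )

    def write_tsv(self, values_path, sidecar_path) -> None:
        """Write window × feature values plus a name/category/assay sidecar."""
        df = self.to_dataframe()
        df.insert(0, "window_index", np.arange(len(df)))
        df.to_csv(values_path, sep="\t", index=False)
        self.annotations().to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, values_path, sidecar_path, window_ref: WindowSet | None = None
    ) -> "FeatureMatrix":
        df = pd.read_csv(values_path, sep="\t")
        if "window_index" in df.columns:
            df = df.drop(columns=["window_index"])
        ann = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
        meta = {r["name"]: (r["category"], r["assay"]) for _, r in ann.iterrows()}
        tracks = []
        for name in df.columns:
            category, assay = meta.get(name, ("", ""))
            tracks.append(
                FeatureTrack(name, df[name].to_numpy(float), category, assay)
            )
        return cls(tracks, window_ref=window_ref)
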