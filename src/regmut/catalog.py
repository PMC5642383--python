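"""Somatic mutation catalogs and per-sample metadata.

A catalog is a table of called somatic variants (chrom, pos, ref, alt,
sample_id; positions stored 0-based) plus a per-sample metadata table with
the grouping labels used downstream: cohort, IGHV status (mutant / unmutant
/ NA), dysplasia grade (ND / LGD / HGD / NA) and a pair identifier linking a
precancer sample to its matched cancer sample.

Variant calling itself is out of scope: catalogs are consumed from MAF-like
TSVs or VCFs produced by an external caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id"]
METADATA_COLUMNS = ["sample_id", "cohort", "ighv_status", "dysplasia", "pair_id"]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=RECORD_COLUMNS)


@dataclass
class MutationCatalog:
    records: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        rec = self.records.reset_index(drop=True)
        if len(rec) == 0 and not set(RECORD_COLUMNS).issubset(rec.columns):
            rec = _empty_records()
        missing = set(RECORD_COLUMNS) - set(rec.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        meta = self.metadata.copy()
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        for col in ("cohort", "ighv_status", "dysplasia", "pair_id"):
            if col not in meta.columns:
                meta[col] = "NA"
        meta = meta.fillna("NA")
        if len(rec):
            if (rec["pos"] < 0).any():
                raise ValueError("mutation positions must be >= 0")
            if (rec["ref"] == rec["alt"]).any():
                raise ValueError("ref and alt alleles must differ")
            unknown = set(rec["sample_id"]) - set(meta.index)
            if unknown:
                raise ValueError(f"records reference samples absent from metadata: {sorted(unknown)[:5]}")
        self.records = rec
        self.metadata = meta

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "MutationCatalog":
        ids = list(sample_ids)
        unknown = set(ids) - set(self.metadata.index)
        if unknown:
            raise KeyError(f"unknown sample_id(s): {sorted(unknown)}")
        rec = self.records[self.records["sample_id"].isin(ids)]
        return MutationCatalog(rec, self.metadata.loc[ids].reset_index())

    def select_samples(self, predicate) -> list[str]:
        """Sample ids whose metadata row satisfies ``predicate`` (row -> bool)."""
        return [sid for sid, row in self.metadata.iterrows() if predicate(row)]

    def write_tsv(self, records_path, metadata_path) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)
        self.metadata.reset_index().to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, records_path, metadata_path) -> "MutationCatalog":
        rec = pd.read_csv(
            records_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                           "sample_id": str},
        )
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        return cls(rec, meta)


def read_maf_tsv(
    path, metadata: pd.DataFrame, one_based: bool = True
) -> MutationCatalog:
    """Read a MAF-like TSV (chrom, pos, ref, alt, sample_id).

    ``one_based=True`` converts positions to the internal 0-based convention.
    Multi-allelic alt entries ("A,T") are expanded to one record per allele.
    """
    rec = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "sample_id": str},
    )
    rec = rec.rename(columns={c: c.lower() for c in rec.columns})
    rec = rec[RECORD_COLUMNS].copy()
    if one_based:
        rec["pos"] = rec["pos"].astype(np.int64) - 1
    multi = rec["alt"].str.contains(",")
    if multi.any():
        rec = rec.assign(alt=rec["alt"].str.split(",")).explode("alt")
    return MutationCatalog(rec, metadata)


def read_vcf(path, sample_id: str, metadata: pd.DataFrame) -> MutationCatalog:
    """Read one sample's somatic calls from a VCF (positions become 0-based).

    Multi-allelic sites are expanded to one record per alt allele.
    """
    from cyvcf2 import VCF  # optional dependency

    rows = []
    for variant in VCF(str(path)):
        for alt in variant.ALT:
            rows.append((variant.CHROM, variant.POS - 1, variant.REF, alt, sample_id))
    rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return MutationCatalog(rec, metadata)


def concat_catalogs(catalogs: Iterable[MutationCatalog]) -> MutationCatalog:
    cats = list(catalogs)
    rec = pd.concat([c.records for c in cats], ignore_index=True)
    meta = pd.concat([c.metadata for c in cats])
    meta = meta[~meta.index.duplicated(keep="first")]
    return MutationCatalog(rec, meta.reset_index())
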