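"""Fragment-count matrices and the paired milk-type / parity sample sheet.

A :class:`CountMatrix` wraps a transcripts x samples pandas DataFrame of
non-negative integer fragment counts together with a sample sheet carrying
sample_id, dam_id, milk_type (colostrum | milk) and parity (1-4).  FPKM is
computed as count / (spliced length in kb x total mapped fragments in
millions); by default the per-library totals are the column sums of the
full matrix, overridable with externally counted totals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

MILK_TYPES = ("colostrum", "milk")
PARITIES = (1, 2, 3, 4)

SAMPLE_SHEET_COLUMNS = ["sample_id", "dam_id", "milk_type", "parity"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["parity"] = sheet["parity"].astype(int)
    bad_type = set(sheet["milk_type"]) - set(MILK_TYPES)
    if bad_type:
        raise ValueError(f"unknown milk_type values: {sorted(bad_type)}")
    bad_par = set(sheet["parity"]) - set(PARITIES)
    if bad_par:
        raise ValueError(f"parity outside 1-4: {sorted(bad_par)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    return sheet


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # transcripts x samples, non-negative integers
    samples: pd.DataFrame  # sample sheet

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate transcript ids in count matrix")
        sheet_ids = list(self.samples["sample_id"])
        missing = [s for s in sheet_ids if s not in self.counts.columns]
        if missing:
            raise ValueError(f"sample sheet samples absent from matrix: {missing}")
        # align column order to the sheet
        self.counts = self.counts[sheet_ids]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path, sheet_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
        self.samples.to_csv(sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, sheet_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t")
        return cls(counts, sheet)

    def sum_to_genes(self, gene_map: dict[str, str]) -> pd.DataFrame:
        """Sum transcript counts to gene level; every row id must be mapped."""
        unmapped = [t for t in self.counts.index if t not in gene_map]
        if unmapped:
            raise KeyError(f"transcripts without gene mapping: {unmapped[:10]}")
        genes = self.counts.index.map(gene_map)
        return self.counts.groupby(genes).sum()


def presence_filter(cm: CountMatrix) -> set[str]:
    """Transcripts detected (count > 0) in at least two samples.

    Detection in a single library is treated as transcriptional noise.
    """
    n_detected = (cm.counts > 0).sum(axis=1)
    return set(cm.counts.index[n_detected >= 2])


def compute_fpkm(
    cm: CountMatrix,
    spliced_lengths: dict[str, int] | pd.Series,
    totals: dict[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    ``totals`` defaults to the column sums of the count matrix; pass
    per-library total aligned fragments to override.
    """
    lengths = pd.Series(spliced_lengths).reindex(cm.counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:10]
        raise ValueError(f"no spliced length for transcripts: {missing}")
    if (lengths <= 0).any():
        raise ValueError("spliced lengths must be positive")
    if totals is None:
        tot = cm.counts.sum(axis=0).astype(float)
    else:
        tot = pd.Series(totals).reindex(cm.counts.columns).astype(float)
        if tot.isna().any() or (tot <= 0).any():
            raise ValueError("totals must be positive for every sample")
    denom = np.outer(lengths.values / 1e3, tot.values / 1e6)
    return pd.DataFrame(
        cm.counts.values / denom, index=cm.counts.index, columns=cm.counts.columns
    )


def abundance_filter(fpkm: pd.DataFrame, tau: float = 0.3) -> set[str]:
    """Transcripts reaching FPKM >= ``tau`` in at least one sample.

    Mirrors the removal of transcripts with FPKM < tau in all samples.
    """
    return set(fpkm.index[fpkm.max(axis=1) >= tau])
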