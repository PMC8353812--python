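"""Relative cell-type composition from cell-specific marker genes.

Whole milk is a mixed cell population (immune, stromal, epithelial and
stem cells).  The proportion of each marker in a sample is the number of
reads mapped to that marker divided by the sum of reads mapped to all
markers in the panel — raw counts, no length correction.  A sample with no
marker reads has an undefined profile and is excluded from group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd

#: default marker panel; "SL100A4" is kept as printed in the source table
#: (presumed variant of S100A4 — see MARKER_ALIASES).
DEFAULT_PANEL: dict[str, str] = {
    "PTPRC": "immune",
    "CD8A": "immune",
    "NCAM1": "immune",
    "CD19": "immune",
    "CD4": "immune",
    "CD3E": "immune",
    "CD3D": "immune",
    "CD3G": "immune",
    "FABP4": "stromal",
    "SL100A4": "stromal",
    "DLK1": "stromal",
    "LAMP1": "epithelial",
    "EPCAM": "epithelial",
    "KRT8": "epithelial",
    "CD34": "stem",
}

MARKER_ALIASES: dict[str, str] = {"S100A4": "SL100A4"}

CELL_TYPES = ("immune", "stromal", "epithelial", "stem")


@dataclass
class MarkerPanel:
    markers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PANEL))

    def __post_init__(self) -> None:
        bad = {ct for ct in self.markers.values()} - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {sorted(bad)}")
        if not self.markers:
            raise ValueError("panel needs >= 1 marker")

    @property
    def symbols(self) -> list[str]:
        return list(self.markers)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["symbol"], df["cell_type"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"symbol": list(self.markers), "cell_type": list(self.markers.values())}
        ).to_csv(path, sep="\t", index=False)


def marker_proportions(
    gene_counts: pd.DataFrame,
    panel: MarkerPanel | None = None,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample marker proportions (markers x samples).

    ``gene_counts`` is a gene x sample count table.  Panel symbols missing
    from the table count as zero (with a warning); alias rows (e.g. S100A4
    for SL100A4) are accepted.  Columns where every marker count is zero
    are all-NaN (undefined profile).
    """
    panel = panel or MarkerPanel()
    aliases = MARKER_ALIASES if aliases is None else aliases
    rows = {}
    for sym in panel.symbols:
        if sym in gene_counts.index:
            rows[sym] = gene_counts.loc[sym]
        else:
            alias = next((a for a, s in aliases.items() if s == sym), None)
            if alias is not None and alias in gene_counts.index:
                rows[sym] = gene_counts.loc[alias]
            else:
                warnings.warn(f"marker {sym} absent from counts; treated as 0")
                rows[sym] = pd.Series(0.0, index=gene_counts.columns)
    mat = pd.DataFrame(rows).T.astype(float)
    totals = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = mat.div(totals, axis=1)
    props.loc[:, totals == 0] = np.nan
    return props


def group_summary(
    profiles: pd.DataFrame, samples: pd.DataFrame, panel: MarkerPanel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean marker proportions per milk-type x parity cell, plus cell-type
    totals.

    Undefined profiles (all-NaN columns) are excluded from the means; an
    empty group yields NaN with a warning.  Returns (marker-level means,
    cell-type-level means), both indexed by marker/cell type with one
    column per group, named like 'colostrum_P1'.
    """
    panel = panel or MarkerPanel()
    by_sample = samples.set_index("sample_id")
    groups: dict[str, list[str]] = {}
    for sid in profiles.columns:
        mt = by_sample.loc[sid, "milk_type"]
        par = int(by_sample.loc[sid, "parity"])
        groups.setdefault(f"{mt}_P{par}", []).append(sid)
    out = {}
    for name in sorted(groups):
        cols = profiles[groups[name]]
        defined = cols.loc[:, cols.notna().any(axis=0)]
        if defined.shape[1] == 0:
            warnings.warn(f"group {name} has no defined profile")
            out[name] = pd.Series(np.nan, index=profiles.index)
        else:
            out[name] = defined.mean(axis=1)
    marker_means = pd.DataFrame(out)
    cell_of = pd.Series({m: panel.markers[m] for m in marker_means.index})
    cell_means = marker_means.groupby(cell_of).sum()
    return marker_means, cell_means
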