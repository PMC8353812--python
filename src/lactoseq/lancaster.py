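"""Gene-level p-value aggregation with the weighted Lancaster method.

The Lancaster method generalizes Fisher's combination: each transcript
p-value p_i is transformed through the upper-tail quantile of a
Gamma(shape w_i / 2, scale 2) distribution, the transformed values are
summed, and the sum T is referred to a chi-squared distribution with
df = sum of the weights.  With all weights equal to 2 the transform is
-2 ln p_i and the method reduces exactly to Fisher's.  Here the weights
are the transcript base means (mean normalized counts), so abundant
transcripts dominate their gene's aggregate p-value.

Transcripts with zero weight or a missing p-value are dropped before
summation; a gene retaining nothing is reported undefined (NaN) and
excluded from the BH correction rather than silently set to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix
from .de import (
    LN2,
    DetThresholds,
    _fit_llf,
    bh_adjust,
    design_matrices,
)

if TYPE_CHECKING:  # pragma: no cover
    from .de import MilkDEResults

P_CLIP_LO = 1e-300


def gamma_upper_quantile(p: float, w: float) -> float:
    """Value with upper-tail probability ``p`` under Gamma(shape w/2, scale 2).

    Continuous and decreasing in p; at w = 2 this is -2 ln p, the Fisher
    transform.
    """
    if w <= 0:
        raise ValueError(f"weight must be positive, got {w}")
    if p <= 0:
        raise ValueError("p = 0 transforms to infinity; clip upstream")
    if p > 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return float(stats.gamma.isf(p, a=w / 2.0, scale=2.0))


@dataclass(frozen=True)
class LancasterResult:
    statistic: float
    df: float
    p_agg: float
    n_retained: int


def lancaster_pvalue(
    pvalues, weights, clip: float = P_CLIP_LO
) -> LancasterResult:
    """Aggregate transcript p-values into one gene-level p-value.

    Pairs with zero/absent weight or absent p are dropped; p-values are
    clipped to [clip, 1] before the quantile transform.  If nothing is
    retained the result is undefined (NaN p_agg, n_retained 0).
    """
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("pvalues and weights must have equal length")
    if (w[~np.isnan(w)] < 0).any():
        raise ValueError("weights must be non-negative")
    keep = ~np.isnan(p) & ~np.isnan(w) & (w > 0)
    if not keep.any():
        return LancasterResult(np.nan, 0.0, np.nan, 0)
    p = np.clip(p[keep], clip, 1.0)
    w = w[keep]
    t = stats.gamma.isf(p, a=w / 2.0, scale=2.0).sum()
    df = w.sum()
    p_agg = float(stats.chi2.sf(t, df))
    return LancasterResult(float(t), float(df), p_agg, int(keep.sum()))


def gene_log2fc(
    cm: CountMatrix, gene_map: dict[str, str], sf: pd.Series, dispersion=None
) -> pd.Series:
    """Gene-level milk-vs-colostrum log2 fold change.

    Transcript counts are summed per gene and the additive-model NB GLM
    type coefficient (offset log size factor) is converted to log2.  Genes
    with all-zero summed counts are NaN.  ``dispersion`` may be a
    precomputed per-gene Series; otherwise gene dispersions are estimated
    by method of moments on the summed counts.
    """
    gene_counts = cm.sum_to_genes(gene_map)
    gcm = CountMatrix(gene_counts, cm.samples)
    if dispersion is None:
        from .de import estimate_dispersion

        dispersion = estimate_dispersion(gcm, sf)
    designs = design_matrices(cm.samples)
    X = designs["additive"].to_numpy()
    coef_idx = list(designs["additive"].columns).index("type_milk")
    offset = np.log(sf.reindex(gene_counts.columns).to_numpy())
    out = {}
    for gid, row in gene_counts.iterrows():
        y = row.to_numpy(dtype=float)
        if not (y > 0).any():
            out[gid] = np.nan
            continue
        try:
            fit = _fit_llf(y, X, offset, float(dispersion[gid]))
            out[gid] = float(fit.params[coef_idx] / LN2)
        except Exception:
            out[gid] = np.nan
    return pd.Series(out, name="log2fc_type")


def aggregate_genes(
    tx_results: "MilkDEResults", gene_map: dict[str, str]
) -> "GeneDEResults":
    """Lancaster-aggregate per-effect transcript p-values to genes.

    Weights are the transcript base means.  Every transcript in the results
    table must be mapped to exactly one gene.  BH correction runs across
    defined genes per effect.
    """
    tx = tx_results.transcripts
    unmapped = sorted(set(tx.index) - set(gene_map))
    if unmapped:
        raise KeyError(f"transcripts without gene mapping: {unmapped[:10]}")
    genes = pd.Series({t: gene_map[t] for t in tx.index}, name="gene_id")
    rows = []
    for gid, members in tx.groupby(genes):
        rec = {"gene_id": gid, "n_transcripts": len(members)}
        w = members["base_mean"].to_numpy()
        for eff in ("interaction", "type", "parity"):
            agg = lancaster_pvalue(members[f"p_{eff}"].to_numpy(), w)
            rec[f"p_{eff}"] = agg.p_agg
        rows.append(rec)
    res = pd.DataFrame(rows).set_index("gene_id").sort_index()
    for eff in ("interaction", "type", "parity"):
        res[f"fdr_{eff}"] = bh_adjust(res[f"p_{eff}"].to_numpy())
    lfc = gene_log2fc(tx_results.model.cm, gene_map, tx_results.size_factors)
    res["log2fc_type"] = lfc.reindex(res.index)
    return GeneDEResults(res, tx_results.thresholds)


def deg_partition(
    gene_results: pd.DataFrame, th: DetThresholds = DetThresholds()
) -> dict[str, set[str]]:
    """Partition genes into interaction and milk-type DEG sets.

    Interaction DEG: interaction FDR <= cut.  Type DEG: type FDR <= cut,
    not an interaction DEG, and |log2FC| strictly greater than the gene
    threshold (genes at or below it are filtered out).
    """
    inter = set(gene_results.index[gene_results["fdr_interaction"] <= th.fdr_cut])
    type_deg = set(
        gene_results.index[
            (gene_results["fdr_type"] <= th.fdr_cut)
            & (gene_results["log2fc_type"].abs() > th.lfc_gene)
            & ~gene_results.index.isin(inter)
        ]
    )
    return {"interaction": inter, "type": type_deg}


@dataclass
class GeneDEResults:
    """Gene-level aggregated DE results.

    ``genes`` is indexed by gene id with p_*, fdr_*, n_transcripts and
    log2fc_type columns; undefined genes (no positively weighted
    transcript) carry NaN p-values.
    """

    genes: pd.DataFrame
    thresholds: DetThresholds = field(default_factory=DetThresholds)

    def deg_sets(self, thresholds: DetThresholds | None = None) -> dict[str, set[str]]:
        return deg_partition(self.genes, thresholds or self.thresholds)

    def summary(self) -> str:
        deg = self.deg_sets()
        n_def = int(self.genes["p_type"].notna().sum())
        lines = [
            "Lancaster gene-level aggregation",
            "=" * 50,
            f"genes:            {len(self.genes)}",
            f"defined:          {n_def}",
            f"FDR cut: {self.thresholds.fdr_cut}   "
            f"|log2FC| (gene): > {self.thresholds.lfc_gene}",
            f"DEG interaction:  {len(deg['interaction'])}",
            f"DEG milk type:    {len(deg['type'])}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        deg = self.deg_sets()
        out = self.genes.copy()
        member = pd.Series("", index=out.index)
        for name, ids in deg.items():
            member[member.index.isin(ids)] = name
        out["deg_set"] = member
        return out
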