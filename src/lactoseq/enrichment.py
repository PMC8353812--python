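"""Hypergeometric over-representation analysis of DEG against term-to-gene maps.

For each term with K annotated genes in a background of N, the probability
of observing k or more term genes among n differentially expressed genes is
the upper tail of the hypergeometric distribution (the observed k is
included).  P-values are Benjamini-Hochberg adjusted across the tested
terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class TermMap:
    """term id -> gene set, against a background gene universe.

    Term genes outside the background are dropped with a warning at
    construction time.
    """

    terms: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("empty background gene set")
        cleaned = {}
        n_dropped = 0
        for term, genes in self.terms.items():
            kept = set(genes) & self.background
            n_dropped += len(genes) - len(kept)
            cleaned[term] = kept
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} term gene(s) outside the background")
        self.terms = cleaned

    @classmethod
    def from_tsv(cls, path, background: set[str]) -> "TermMap":
        """Two-column TSV: term_id, gene_id."""
        df = pd.read_csv(path, sep="\t")
        terms: dict[str, set[str]] = {}
        for term, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            terms.setdefault(term, set()).add(gene)
        return cls(terms, background)

    @classmethod
    def from_gmt(cls, path, background: set[str]) -> "TermMap":
        terms: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    terms[parts[0]] = set(parts[2:])
        return cls(terms, background)


def hypergeom_ora(de_set: set[str], term_map: TermMap) -> pd.DataFrame:
    """Over-representation test of ``de_set`` against every term.

    Returns a DataFrame (term id index) with N, K, n, k, p, fdr and fold
    enrichment = (k/n)/(K/N).  DE genes outside the background are dropped
    with a warning; empty terms are skipped.
    """
    bg = term_map.background
    outside = set(de_set) - bg
    if outside:
        warnings.warn(f"dropped {len(outside)} DE gene(s) outside the background")
    de = set(de_set) & bg
    N, n = len(bg), len(de)
    rows = []
    for term, genes in sorted(term_map.terms.items()):
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & de)
        # P(X >= k) for X ~ Hypergeom(N, K, n), observed k included
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append({"term_id": term, "N": N, "K": K, "n": n, "k": k, "p": p, "fold_enrichment": fold})
    res = pd.DataFrame(rows, columns=["term_id", "N", "K", "n", "k", "p", "fold_enrichment"])
    if len(res):
        res = res.set_index("term_id")
        res["fdr"] = bh_adjust(res["p"].to_numpy())
    else:
        res = res.set_index("term_id")
        res["fdr"] = []
    return res
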