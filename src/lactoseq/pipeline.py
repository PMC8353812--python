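"""End-to-end orchestration: fixture or user bundle -> verdicts, DET/DEG,
composition and enrichment tables, plus a machine-readable run report.

Stages hand off through plain TSV/GTF files so every intermediate is
inspectable and diff-able.  The report records input checksums, the
thresholds in force, the seed and the count funnel (transcripts surviving
each filter and the DET/DEG set sizes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import gtf
from .annotation import ReferenceAnnotation
from .composition import MarkerPanel, group_summary, marker_proportions
from .counts import CountMatrix
from .de import DetThresholds, MilkDEModel
from .discovery import (
    DEFAULT_MIN_FPKM,
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_ORF_AA,
    DEFAULT_PFAM_EVALUE,
    discovery_pipeline,
    read_evidence_tsv,
    verdicts_to_frame,
)
from .enrichment import TermMap, hypergeom_ora
from .lancaster import GeneDEResults


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for a full run."""

    reference_gtf: str
    query_gtf: str
    counts_tsv: str
    samples_tsv: str
    evidence_tsv: str
    outdir: str
    panel_tsv: str | None = None
    term_map_tsv: str | None = None
    min_fpkm: float = DEFAULT_MIN_FPKM
    min_length: int = DEFAULT_MIN_LENGTH
    min_orf_aa: int = DEFAULT_MIN_ORF_AA
    pfam_evalue: float = DEFAULT_PFAM_EVALUE
    fdr: float = 0.01
    lfc_transcript: float = 2.0
    lfc_gene: float = 1.5
    enrich_fdr: float = 0.05
    seed: int = 0

    def thresholds(self) -> DetThresholds:
        return DetThresholds(self.fdr, self.lfc_transcript, self.lfc_gene)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig) -> dict:
    """Run discovery -> differential expression -> Lancaster aggregation ->
    composition (-> enrichment when a term map is supplied) and write all
    result tables under ``config.outdir``.

    Returns the run report (also written as report.json).  The first
    inconsistency aborts with the stage name; partial outputs are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    try:
        report: dict = {
            "seed": config.seed,
            "thresholds": {
                "min_fpkm": config.min_fpkm,
                "min_length": config.min_length,
                "min_orf_aa": config.min_orf_aa,
                "pfam_evalue": config.pfam_evalue,
                "fdr": config.fdr,
                "lfc_transcript": config.lfc_transcript,
                "lfc_gene": config.lfc_gene,
                "enrich_fdr": config.enrich_fdr,
            },
            "inputs": {},
            "stages": {},
        }
        for key in ("reference_gtf", "query_gtf", "counts_tsv", "samples_tsv", "evidence_tsv"):
            path = getattr(config, key)
            report["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

        # ---- discovery -------------------------------------------------
        stage = "discovery"
        try:
            ref_models = gtf.read_gtf(config.reference_gtf)
            queries = gtf.read_gtf(config.query_gtf)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, f"unreadable GTF input: {exc}") from exc
        if not queries:
            raise PipelineError(stage, f"no transcripts in {config.query_gtf}")
        ref = ReferenceAnnotation(ref_models)
        cm = CountMatrix.from_tsv(config.counts_tsv, config.samples_tsv)
        evidence = read_evidence_tsv(config.evidence_tsv)
        try:
            verdicts = discovery_pipeline(
                queries,
                ref,
                cm,
                evidence,
                min_fpkm=config.min_fpkm,
                min_length=config.min_length,
                min_orf_aa=config.min_orf_aa,
                pfam_evalue=config.pfam_evalue,
            )
        except KeyError as exc:
            raise PipelineError(stage, str(exc)) from exc
        vf = verdicts_to_frame(verdicts).set_index("transcript_id")
        _emit(vf, "verdicts.tsv")

        n = len(vf)
        reasons = vf["reason"]
        funnel = {
            "input": n,
            "after_presence": n - int((reasons == "presence").sum()),
        }
        funnel["after_abundance"] = funnel["after_presence"] - int(
            (reasons == "abundance").sum()
        )
        funnel["after_class_code"] = funnel["after_abundance"] - int(
            (reasons == "class_code").sum()
        )
        funnel["known"] = int((vf["class"] == "known").sum())
        funnel["after_structural"] = funnel["after_class_code"] - int(
            reasons.isin(["single_exon"]).sum()
            + reasons.str.startswith("length<").sum()
        )
        funnel["with_orf"] = funnel["after_structural"] - int((reasons == "no_orf").sum())
        funnel["novel_coding"] = int((vf["class"] == "novel_coding").sum())
        funnel["novel_lncRNA"] = int((vf["class"] == "novel_lncRNA").sum())
        funnel["kept"] = funnel["known"] + funnel["novel_coding"] + funnel["novel_lncRNA"]
        report["stages"][stage] = funnel

        # ---- differential expression ------------------------------------
        stage = "diffexpr"
        kept = vf.index[vf["class"] != "discarded"]
        if len(kept) == 0:
            raise PipelineError(stage, "no transcript survived discovery")
        de_cm = CountMatrix(cm.counts.loc[kept], cm.samples)
        th = config.thresholds()
        model = MilkDEModel(de_cm)
        try:
            results = model.fit(thresholds=th)
        except ValueError:
            results = model.fit(pseudo_reference=True, thresholds=th)
        _emit(results.to_frame(), "transcript_de.tsv")
        det = results.det_sets()
        report["stages"][stage] = {
            "tested": int(results.transcripts["p_type"].notna().sum()),
            "det_interaction": len(det["interaction"]),
            "det_type": len(det["type"]),
            "det_parity": len(det["parity"]),
        }

        # ---- gene aggregation -------------------------------------------
        stage = "lancaster"
        gene_map = {q.transcript_id: q.gene_id for q in queries if q.transcript_id in set(kept)}
        genes: GeneDEResults = results.aggregate_genes(gene_map)
        _emit(genes.to_frame(), "gene_de.tsv")
        deg = genes.deg_sets()
        report["stages"][stage] = {
            "genes": len(genes.genes),
            "deg_interaction": len(deg["interaction"]),
            "deg_type": len(deg["type"]),
        }

        # ---- cell composition --------------------------------------------
        stage = "cell_composition"
        panel = MarkerPanel.from_tsv(config.panel_tsv) if config.panel_tsv else MarkerPanel()
        gene_counts = de_cm.sum_to_genes(gene_map)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles = marker_proportions(gene_counts, panel)
            marker_means, cell_means = group_summary(profiles, cm.samples, panel)
        _emit(profiles, "composition_samples.tsv", index_label="marker")
        _emit(marker_means, "composition_groups.tsv", index_label="marker")
        _emit(cell_means, "composition_cell_types.tsv", index_label="cell_type")
        report["stages"][stage] = {
            "markers": len(panel.symbols),
            "defined_samples": int(profiles.notna().any(axis=0).sum()),
        }

        # ---- enrichment ---------------------------------------------------
        stage = "enrichment"
        if config.term_map_tsv:
            background = set(genes.genes.index)
            term_map = TermMap.from_tsv(config.term_map_tsv, background)
            ora = hypergeom_ora(deg["type"], term_map)
            _emit(ora, "enrichment_type.tsv")
            report["stages"][stage] = {
                "terms": len(ora),
                "significant": int((ora["fdr"] <= config.enrich_fdr).sum())
                if len(ora)
                else 0,
            }
        else:
            report["stages"][stage] = {"skipped": "no term map supplied"}

        report_path = outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
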