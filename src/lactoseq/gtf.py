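"""GTF reading and writing for transcript models.

Reading goes through gffutils (in-memory database, GTF dialect); writing
emits minimal transcript + exon feature lines with the mandatory gene_id /
transcript_id attributes and optional gene_biotype.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils

from .intervals import GenomicInterval, TranscriptModel

_BIOTYPE_MAP = {
    "mrna": "mRNA",
    "protein_coding": "mRNA",
    "ncrna": "ncRNA",
    "lncrna": "ncRNA",
    "pseudogene": "pseudogene",
    "miscrna": "miscRNA",
    "misc_rna": "miscRNA",
}


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models (exon features only are
    required; transcript feature lines are optional)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        rec = by_tx.setdefault(
            tx_id,
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "biotype": "unknown",
            },
        )
        if "gene_biotype" in feat.attributes:
            raw = feat.attributes["gene_biotype"][0]
            rec["biotype"] = _BIOTYPE_MAP.get(raw.lower(), "unknown")
        rec["exons"].append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        )
    out = []
    for tx_id, rec in by_tx.items():
        out.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=rec["biotype"],
            )
        )
    return out


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | os.PathLike,
    source: str = "lactoseq",
) -> None:
    """Write transcript + exon GTF lines for ``transcripts``."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            if t.biotype != "unknown":
                attrs += f' gene_biotype "{t.biotype}";'
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.start),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for ex in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(ex.start),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
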