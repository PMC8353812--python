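"""Novel-transcript discovery cascade.

Assembled transcripts are funnelled through: presence filter (detected in
>= 2 libraries) -> abundance filter (FPKM >= 0.3 in >= 1 library) -> class
code (exact matches become "known"; codes outside =,j,x,i,u are discarded)
-> structural filter (spliced length >= 200 bp and >= 2 exons) -> ORF
requirement -> consensus coding-potential call.  Novel candidates that the
consensus calls coding become novel mRNA; non-coding ones become novel
lncRNA with a positional subclass; ambiguous ones are discarded.  Each
verdict records the decisive rule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

from .annotation import ReferenceAnnotation, assign_class_code, classify_lnc_position
from .counts import CountMatrix, abundance_filter, compute_fpkm, presence_filter
from .intervals import TranscriptModel

NOVEL_CODES = ("j", "x", "i", "u")

DEFAULT_MIN_FPKM = 0.3
DEFAULT_MIN_LENGTH = 200
DEFAULT_MIN_ORF_AA = 120
DEFAULT_PFAM_EVALUE = 10.0

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingEvidence:
    """Per-transcript ORF length and external coding-potential scores."""

    transcript_id: str
    orf_len_aa: int | None
    cpc2_label: str | None = None
    plek_score: float | None = None
    cnit_score: float | None = None
    pfam_min_evalue: float | None = None

    def __post_init__(self) -> None:
        if self.cpc2_label is not None and self.cpc2_label not in {
            "coding",
            "noncoding",
        }:
            raise ValueError(f"cpc2_label must be coding/noncoding, got {self.cpc2_label!r}")
        if self.pfam_min_evalue is not None and self.pfam_min_evalue < 0:
            raise ValueError("pfam_min_evalue must be >= 0")


@dataclass
class TranscriptVerdict:
    transcript_id: str
    klass: str  # known | novel_coding | novel_lncRNA | discarded
    code: str | None = None
    lnc_subclass: str | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.klass not in {"known", "novel_coding", "novel_lncRNA", "discarded"}:
            raise ValueError(f"bad verdict class {self.klass!r}")
        if (self.lnc_subclass is not None) != (self.klass == "novel_lncRNA"):
            raise ValueError("lnc_subclass present iff class is novel_lncRNA")
        if self.klass == "discarded" and not self.reason:
            raise ValueError("discarded verdicts need a reason")


def structural_filter(
    t: TranscriptModel, min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[bool, str]:
    """Pass iff spliced (exonic) length >= ``min_length`` and >= 2 exons."""
    if t.spliced_length < min_length:
        return False, f"length<{min_length}"
    if t.n_exons < 2:
        return False, "single_exon"
    return True, ""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _orf_scan(seq: str) -> int | None:
    """Longest ATG..stop ORF over the 3 forward frames; aa length counts
    codons from ATG inclusive to the stop exclusive."""
    best: int | None = None
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                aa = (i - start) // 3
                if best is None or aa > best:
                    best = aa
                start = None
    return best


def find_longest_orf(seq: str, six_frame: bool = False) -> int | None:
    """Length (aa) of the longest complete open reading frame, or None.

    Scans the three forward frames by default (stranded library prep, so
    the given sequence is the transcript strand); ``six_frame=True`` also
    scans the reverse complement for unstranded inputs.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence must be over A/C/G/T/N")
    best = _orf_scan(seq)
    if six_frame:
        rc = seq.translate(_COMPLEMENT)[::-1]
        other = _orf_scan(rc)
        if other is not None and (best is None or other > best):
            best = other
    return best


def consensus_coding_call(
    ev: CodingEvidence,
    min_orf_aa: int = DEFAULT_MIN_ORF_AA,
    pfam_evalue: float = DEFAULT_PFAM_EVALUE,
) -> str:
    """Consensus coding-potential verdict: coding / noncoding / ambiguous.

    A long ORF (>= ``min_orf_aa``) decides coding outright.  Otherwise a
    significant Pfam domain hit (E-value < ``pfam_evalue``) decides coding.
    Otherwise the three sequence classifiers must agree: CPC2 "coding" with
    positive PLEK and CNIT scores is coding; CPC2 "noncoding" with both
    scores negative is noncoding; any disagreement (including a score of
    exactly zero) is ambiguous.
    """
    if ev.orf_len_aa is None:
        raise ValueError(f"{ev.transcript_id}: no ORF; should be filtered upstream")
    if ev.orf_len_aa >= min_orf_aa:
        return "coding"
    if ev.pfam_min_evalue is not None and ev.pfam_min_evalue < pfam_evalue:
        return "coding"
    if ev.cpc2_label is None or ev.plek_score is None or ev.cnit_score is None:
        raise ValueError(f"{ev.transcript_id}: missing classifier scores")
    no_pfam = ev.pfam_min_evalue is None or not (ev.pfam_min_evalue < pfam_evalue)
    if no_pfam and ev.cpc2_label == "coding" and ev.plek_score > 0 and ev.cnit_score > 0:
        return "coding"
    if (
        no_pfam
        and ev.cpc2_label == "noncoding"
        and ev.plek_score < 0
        and ev.cnit_score < 0
    ):
        return "noncoding"
    return "ambiguous"


def discovery_pipeline(
    queries: list[TranscriptModel],
    ref: ReferenceAnnotation,
    cm: CountMatrix,
    evidence: dict[str, CodingEvidence],
    totals: dict[str, float] | None = None,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_orf_aa: int = DEFAULT_MIN_ORF_AA,
    pfam_evalue: float = DEFAULT_PFAM_EVALUE,
) -> dict[str, TranscriptVerdict]:
    """Run the full discovery cascade and return a verdict per query.

    ``evidence`` need only cover transcripts that reach the coding-potential
    stage; an id mismatch between queries and the count matrix is an error.
    """
    qids = [q.transcript_id for q in queries]
    missing = sorted(set(qids) - set(cm.transcript_ids))
    if missing:
        raise KeyError(f"queries absent from count matrix: {missing[:10]}")
    by_id = {q.transcript_id: q for q in queries}

    sub = CountMatrix(cm.counts.loc[qids], cm.samples)
    present = presence_filter(sub)
    lengths = {q.transcript_id: q.spliced_length for q in queries}
    if totals is None:
        # library totals come from the full matrix, not the query subset
        totals = cm.counts.sum(axis=0).astype(float)
    fpkm = compute_fpkm(sub, lengths, totals)
    abundant = abundance_filter(fpkm, tau=min_fpkm)

    verdicts: dict[str, TranscriptVerdict] = {}
    for tid in qids:
        if tid not in present:
            verdicts[tid] = TranscriptVerdict(tid, "discarded", reason="presence")
            continue
        if tid not in abundant:
            verdicts[tid] = TranscriptVerdict(tid, "discarded", reason="abundance")
            continue
        q = by_id[tid]
        cc = assign_class_code(q, ref)
        if cc.code == "=":
            verdicts[tid] = TranscriptVerdict(tid, "known", code="=", reason="reference_match")
            continue
        if cc.code not in NOVEL_CODES:
            verdicts[tid] = TranscriptVerdict(
                tid, "discarded", code=cc.code, reason="class_code"
            )
            continue
        ok, why = structural_filter(q, min_length)
        if not ok:
            verdicts[tid] = TranscriptVerdict(tid, "discarded", code=cc.code, reason=why)
            continue
        ev = evidence.get(tid)
        if ev is None or ev.orf_len_aa is None:
            verdicts[tid] = TranscriptVerdict(tid, "discarded", code=cc.code, reason="no_orf")
            continue
        call = consensus_coding_call(ev, min_orf_aa, pfam_evalue)
        if call == "coding":
            verdicts[tid] = TranscriptVerdict(
                tid, "novel_coding", code=cc.code, reason="coding_potential"
            )
        elif call == "noncoding":
            verdicts[tid] = TranscriptVerdict(
                tid,
                "novel_lncRNA",
                code=cc.code,
                lnc_subclass=classify_lnc_position(cc),
                reason="noncoding_consensus",
            )
        else:
            verdicts[tid] = TranscriptVerdict(
                tid, "discarded", code=cc.code, reason="ambiguous_coding_potential"
            )
    return verdicts


def verdicts_to_frame(verdicts: dict[str, TranscriptVerdict]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": v.transcript_id,
            "class": v.klass,
            "code": v.code if v.code is not None else "",
            "lnc_subclass": v.lnc_subclass if v.lnc_subclass is not None else "",
            "reason": v.reason,
        }
        for v in verdicts.values()
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "class", "code", "lnc_subclass", "reason"])


def read_evidence_tsv(path) -> dict[str, CodingEvidence]:
    """Read a coding-evidence table (columns: transcript_id, orf_len_aa,
    cpc2_label, plek_score, cnit_score, pfam_min_evalue; empty = absent)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        def _f(x):
            return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x

        orf = _f(row.orf_len_aa)
        out[row.transcript_id] = CodingEvidence(
            transcript_id=row.transcript_id,
            orf_len_aa=int(orf) if orf is not None else None,
            cpc2_label=_f(row.cpc2_label),
            plek_score=_f(row.plek_score),
            cnit_score=_f(row.cnit_score),
            pfam_min_evalue=_f(row.pfam_min_evalue),
        )
    return out


def write_evidence_tsv(evidence: dict[str, CodingEvidence], path) -> None:
    rows = []
    for ev in evidence.values():
        rows.append(
            {
                "transcript_id": ev.transcript_id,
                "orf_len_aa": ev.orf_len_aa,
                "cpc2_label": ev.cpc2_label,
                "plek_score": ev.plek_score,
                "cnit_score": ev.cnit_score,
                "pfam_min_evalue": ev.pfam_min_evalue,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "orf_len_aa",
            "cpc2_label",
            "plek_score",
            "cnit_score",
            "pfam_min_evalue",
        ],
    ).to_csv(path, sep="\t", index=False)
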