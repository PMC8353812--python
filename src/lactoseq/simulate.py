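"""Synthetic fixtures with known truth for every pipeline stage.

The generator builds, from one seed:

* a reference annotation and a set of query transcripts whose class codes
  are guaranteed by construction ('=' copies a reference intron chain, 'j'
  drops a terminal exon, 'x' overlaps reference exons on the opposite
  strand, 'i' sits inside a reference intron, 'u' sits in an intergenic
  gap, plus 'other' distractors that overlap a reference exon on the same
  strand without sharing a junction);
* transcript sequences whose longest open reading frame has exactly the
  planted length (the background alphabet is A-free, so the single planted
  ATG starts the only ORF);
* a coding-evidence table that agrees with the planted coding status with
  a configurable probability;
* a negative-binomial count matrix under the paired colostrum/milk x
  parity design, with planted per-transcript log2 fold changes for the
  milk-type, parity and interaction effects, plus constructively forced
  presence- and abundance-filter failures.

The default design mirrors a 65-dam study (16/25/15/9 dams in parities
1-4, each sampled at day 0 and day 10), NB dispersion 0.5 and an expected
differentially expressed fraction of roughly 1,000 / 17,740.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import LNC_SUBCLASS, ReferenceAnnotation
from .counts import CountMatrix
from .discovery import CodingEvidence, write_evidence_tsv
from .gtf import write_gtf
from .intervals import GenomicInterval, TranscriptModel

LN2 = np.log(2.0)

#: query categories -> (class code, expected pipeline verdict, decisive reason)
CATEGORIES = {
    "known": ("=", "known", "reference_match"),
    "novel_j": ("j", None, None),  # verdict depends on coding truth
    "novel_x": ("x", None, None),
    "novel_i": ("i", None, None),
    "novel_u": ("u", None, None),
    "other": ("other", "discarded", "class_code"),
    "presence_fail": ("u", "discarded", "presence"),
    "abundance_fail": ("u", "discarded", "abundance"),
    "struct_single_exon": ("u", "discarded", "single_exon"),
    "struct_short": ("i", "discarded", "length<200"),
    "no_orf": ("u", "discarded", "no_orf"),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed drives every draw."""

    seed: int = 7
    # annotation layout
    n_ref_genes: int = 60
    n_queries: int = 400
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {"=": 0.30, "j": 0.18, "x": 0.10, "i": 0.10, "u": 0.17}
    )
    frac_other: float = 0.04
    frac_presence_fail: float = 0.025
    frac_abundance_fail: float = 0.025
    frac_struct_single: float = 0.02
    frac_struct_short: float = 0.02
    frac_no_orf: float = 0.02
    # coding truth among novel candidates
    coding_fraction: float = 0.5
    frac_long_orf: float = 0.5  # of coding: decided by ORF >= 120 aa
    long_orf_range: tuple[int, int] = (120, 175)
    short_orf_range: tuple[int, int] = (40, 100)
    evidence_agreement: float = 1.0
    # count model
    dams_per_parity: tuple[int, ...] = (16, 25, 15, 9)
    n_transcripts: int | None = None  # standalone count sims without annotation
    de_frac_type: float = 0.056  # ~1000 of 17,740 expected DE
    de_frac_parity: float = 0.03
    de_frac_interaction: float = 0.03
    lfc_type_range: tuple[float, float] = (1.5, 4.0)
    lfc_parity_range: tuple[float, float] = (1.0, 2.5)
    lfc_interaction_range: tuple[float, float] = (1.5, 3.0)
    dispersion: float = 0.5
    baseline_sigma: float = 1.5
    baseline_floor: float = 10.0
    mean_total_fragments: float = 2.0e6
    library_sigma: float = 0.15

    def __post_init__(self) -> None:
        total = (
            sum(self.class_mixture.values())
            + self.frac_other
            + self.frac_presence_fail
            + self.frac_abundance_fail
            + self.frac_struct_single
            + self.frac_struct_short
            + self.frac_no_orf
        )
        if not np.isclose(total, 1.0):
            raise ValueError(f"category fractions must sum to 1, got {total}")
        if not 0 <= self.evidence_agreement <= 1:
            raise ValueError("evidence_agreement must lie in [0, 1]")
        if any(d <= 0 for d in self.dams_per_parity):
            raise ValueError("dams_per_parity must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["dams_per_parity"] = list(d["dams_per_parity"])
        for k in ("long_orf_range", "short_orf_range", "lfc_type_range",
                  "lfc_parity_range", "lfc_interaction_range"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("dams_per_parity", "long_orf_range", "short_orf_range",
                  "lfc_type_range", "lfc_parity_range", "lfc_interaction_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# annotation

_SLOT = 40_000  # genomic slot reserved per reference gene


def _make_reference_gene(rng, chrom: str, slot_start: int, gid: str) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(4, 8))
    start = slot_start + int(rng.integers(200, 2000))
    exons = []
    pos = start
    for i in range(n_ex):
        ex_len = int(rng.integers(200, 401))
        exons.append(GenomicInterval(chrom, pos, pos + ex_len - 1, strand))
        # first intron is wide enough to host intronic queries
        gap = 1500 if i == 0 else int(rng.integers(400, 1201))
        pos = pos + ex_len + gap
    return TranscriptModel(
        transcript_id=f"{gid}.1",
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=exons,
        biotype="mRNA",
    )


def _category_counts(config: SimulationConfig, rng) -> list[str]:
    fracs = {
        "known": config.class_mixture.get("=", 0.0),
        "novel_j": config.class_mixture.get("j", 0.0),
        "novel_x": config.class_mixture.get("x", 0.0),
        "novel_i": config.class_mixture.get("i", 0.0),
        "novel_u": config.class_mixture.get("u", 0.0),
        "other": config.frac_other,
        "presence_fail": config.frac_presence_fail,
        "abundance_fail": config.frac_abundance_fail,
        "struct_single_exon": config.frac_struct_single,
        "struct_short": config.frac_struct_short,
        "no_orf": config.frac_no_orf,
    }
    names = list(fracs)
    counts = rng.multinomial(config.n_queries, [fracs[n] for n in names])
    cats: list[str] = []
    for name, c in zip(names, counts):
        cats.extend([name] * int(c))
    rng.shuffle(cats)
    return cats


def _two_exon_in_gap(rng, chrom, lo, hi, strand, ex_len=(250, 350), gap=(80, 200)):
    l1 = int(rng.integers(*ex_len))
    l2 = int(rng.integers(*ex_len))
    g = int(rng.integers(*gap))
    span = l1 + g + l2
    start = int(rng.integers(lo, hi - span))
    return [
        GenomicInterval(chrom, start, start + l1 - 1, strand),
        GenomicInterval(chrom, start + l1 + g, start + l1 + g + l2 - 1, strand),
    ]


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceAnnotation, list[TranscriptModel], pd.DataFrame]:
    """Reference annotation, query transcripts and the planted truth table.

    Placement is constructive: the truth table's class code and expected
    verdict hold exactly for every query.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = ["chr1", "chr2"]
    refs: list[TranscriptModel] = []
    slots: list[tuple[str, int]] = []
    per_chrom = int(np.ceil(config.n_ref_genes / len(chroms)))
    g = 0
    for chrom in chroms:
        for s in range(per_chrom):
            if g >= config.n_ref_genes:
                break
            slot_start = 1 + s * _SLOT
            refs.append(_make_reference_gene(rng, chrom, slot_start, f"gene{g:04d}"))
            slots.append((chrom, slot_start))
            g += 1
    ref = ReferenceAnnotation(refs)

    cats = _category_counts(config, rng)
    queries: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    opposite = {"+": "-", "-": "+"}
    novel_gene_counter = 0

    for qi, cat in enumerate(cats):
        tid = f"MSTRG.{qi + 1}.1"
        ridx = int(rng.integers(len(refs)))
        r = refs[ridx]
        chrom, slot_start = slots[ridx]
        gap_lo = slot_start + 22_000
        gap_hi = slot_start + _SLOT - 1_000
        code, verdict, reason = CATEGORIES[cat]
        gene_id = None

        if cat == "known":
            exons = list(r.exons)
            strand = r.strand
            gene_id = r.gene_id
        elif cat == "novel_j":
            exons = list(r.exons[:-1])  # drop terminal exon; >= 1 shared intron
            strand = r.strand
            gene_id = r.gene_id
        elif cat == "novel_x":
            strand = opposite[r.strand]
            e1, e2 = r.exons[0], r.exons[1]
            exons = [
                GenomicInterval(chrom, e1.start - 50, e1.end + 50, strand),
                GenomicInterval(chrom, e2.start - 50, e2.end + 50, strand),
            ]
        elif cat == "novel_i":
            intron_lo = r.exons[0].end + 1
            intron_hi = r.exons[1].start - 1  # the forced 1500-bp first intron
            strand = r.strand
            exons = _two_exon_in_gap(
                rng, chrom, intron_lo + 20, intron_hi - 20,
                strand, ex_len=(280, 320), gap=(60, 120),
            )
        elif cat in {"novel_u", "presence_fail", "no_orf"}:
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _two_exon_in_gap(rng, chrom, gap_lo, gap_hi, strand)
        elif cat == "abundance_fail":
            strand = "+"
            exons = _two_exon_in_gap(
                rng, chrom, gap_lo, gap_hi, strand, ex_len=(4000, 4500), gap=(300, 600)
            )
        elif cat == "struct_single_exon":
            strand = "+"
            start = int(rng.integers(gap_lo, gap_hi - 400))
            exons = [GenomicInterval(chrom, start, start + 299, strand)]
        elif cat == "struct_short":
            intron_lo = r.exons[0].end + 1
            intron_hi = r.exons[1].start - 1
            strand = r.strand
            exons = _two_exon_in_gap(
                rng, chrom, intron_lo + 20, intron_hi - 20,
                strand, ex_len=(70, 90), gap=(40, 80),
            )
        elif cat == "other":
            ex = max(r.exons, key=len)
            strand = r.strand
            start = ex.start + 30
            exons = [GenomicInterval(chrom, start, min(start + 149, ex.end), strand)]
        else:  # pragma: no cover
            raise AssertionError(cat)

        if gene_id is None:
            gene_id = f"MSTRG.{novel_gene_counter + 10_000}"
            novel_gene_counter += 1
        q = TranscriptModel(tid, gene_id, chrom, strand, exons)
        queries.append(q)

        is_novel = cat.startswith("novel_")
        coding: bool | None = None
        if is_novel:
            coding = bool(rng.random() < config.coding_fraction)
            verdict = "novel_coding" if coding else "novel_lncRNA"
            reason = "coding_potential" if coding else "noncoding_consensus"
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene_id,
                "category": cat,
                "class_code": code,
                "expected_class": verdict,
                "reason": reason,
                "coding": coding,
                "lnc_subclass": LNC_SUBCLASS[code]
                if (is_novel and coding is False)
                else "",
                "spliced_length": q.spliced_length,
            }
        )

    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    return ref, queries, truth


# ---------------------------------------------------------------------------
# sequences

_BG = np.array(list("CGT"))
_BG_CODONS = ["".join((a, b, c)) for a in "CGT" for b in "CGT" for c in "CGT"]


def _planted_orf_sequence(rng, length: int, orf_aa: int | None) -> str:
    """Random sequence of ``length`` nt whose longest ORF is exactly
    ``orf_aa`` amino acids (or absent).

    The background alphabet is {C, G, T}: with no A outside the planted
    ATG...stop, the planted ORF is the only one.
    """
    seq = rng.choice(_BG, size=length)
    if orf_aa is None:
        return "".join(seq)
    need = 3 * (orf_aa + 1)
    if need > length:
        raise ValueError(f"ORF of {orf_aa} aa needs {need} nt > length {length}")
    start = int(rng.integers(0, length - need + 1))
    seq[start : start + 3] = list("ATG")
    stop_at = start + 3 * orf_aa
    seq[stop_at : stop_at + 3] = list("TAA")
    if stop_at + 3 < length:
        seq[stop_at + 3] = "C"  # guard against A+TG forming a spurious start
    return "".join(seq)


def simulate_sequences(
    queries: list[TranscriptModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcript-strand sequences with planted ORF lengths.

    Returns (sequences, truth) where truth gains an ``orf_len_aa`` column
    (pandas nullable integer; NA for the planted no-ORF transcripts).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    seqs: dict[str, str] = {}
    orf_lens: dict[str, int | None] = {}
    for q in queries:
        row = truth.loc[q.transcript_id]
        length = q.spliced_length
        if row["category"] == "no_orf":
            orf = None
        elif row["coding"] is True or row["category"] == "known":
            lo, hi = config.long_orf_range
            if row["coding"] is True and rng.random() >= config.frac_long_orf:
                lo, hi = config.short_orf_range  # coding decided by evidence
            hi = min(hi, length // 3 - 1)
            if hi < lo:
                raise ValueError(
                    f"{q.transcript_id}: length {length} too short for ORF in "
                    f"[{lo}, {hi}]"
                )
            orf = int(rng.integers(lo, hi + 1))
        else:
            lo, hi = config.short_orf_range
            hi = min(hi, length // 3 - 1)
            orf = int(rng.integers(lo, hi + 1))
        seqs[q.transcript_id] = _planted_orf_sequence(rng, length, orf)
        orf_lens[q.transcript_id] = orf
    truth = truth.copy()
    truth["orf_len_aa"] = pd.array(
        [orf_lens[t] for t in truth.index], dtype="Int64"
    )
    return seqs, truth


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# coding evidence


def simulate_evidence(
    truth: pd.DataFrame,
    agreement: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict[str, CodingEvidence]:
    """Coding-evidence table consistent with the planted coding status with
    probability ``agreement``; otherwise one field is flipped so the
    consensus becomes ambiguous.

    Transcripts whose planted ORF already decides coding (>= 120 aa) keep a
    consistent profile regardless (the flip could not change their call).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    a = 1.0 if agreement is None else agreement
    out: dict[str, CodingEvidence] = {}
    for tid, row in truth.iterrows():
        orf = row.get("orf_len_aa")
        orf = None if pd.isna(orf) else int(orf)
        if orf is None:
            out[tid] = CodingEvidence(tid, None)
            continue
        coding = True if pd.isna(row["coding"]) else bool(row["coding"])
        if coding:
            ev = dict(
                cpc2_label="coding",
                plek_score=float(rng.uniform(0.2, 1.0)),
                cnit_score=float(rng.uniform(0.2, 1.0)),
                pfam_min_evalue=float(rng.uniform(0.0, 5.0))
                if rng.random() < 0.5
                else None,
            )
        else:
            ev = dict(
                cpc2_label="noncoding",
                plek_score=float(rng.uniform(-1.0, -0.2)),
                cnit_score=float(rng.uniform(-1.0, -0.2)),
                pfam_min_evalue=None,
            )
        orf_decided = orf >= 120
        if not orf_decided and rng.random() >= a:
            # flip one classifier so the consensus is ambiguous
            flip = rng.integers(3)
            if flip == 0:
                ev["cpc2_label"] = "noncoding" if coding else "coding"
            elif flip == 1:
                ev["plek_score"] = -ev["plek_score"]
            else:
                ev["cnit_score"] = -ev["cnit_score"]
            ev["pfam_min_evalue"] = None  # a Pfam hit must not rescue the flip
        out[tid] = CodingEvidence(tid, orf, **ev)
    return out


# ---------------------------------------------------------------------------
# counts


def make_sample_sheet(dams_per_parity: tuple[int, ...]) -> pd.DataFrame:
    rows = []
    for p, n_dams in enumerate(dams_per_parity, start=1):
        for d in range(n_dams):
            dam = f"P{p}D{d + 1:02d}"
            for mt in ("colostrum", "milk"):
                rows.append(
                    {
                        "sample_id": f"{dam}_{mt}",
                        "dam_id": dam,
                        "milk_type": mt,
                        "parity": p,
                    }
                )
    return pd.DataFrame(rows)


def _plant_de_effects(config: SimulationConfig, n: int, rng) -> pd.DataFrame:
    """Mutually exclusive per-transcript effect assignment with planted
    log2 fold-change magnitudes and random signs."""
    p_none = 1.0 - config.de_frac_type - config.de_frac_parity - config.de_frac_interaction
    if p_none < 0:
        raise ValueError("DE fractions exceed 1")
    which = rng.choice(
        ["none", "type", "parity", "interaction"],
        size=n,
        p=[p_none, config.de_frac_type, config.de_frac_parity, config.de_frac_interaction],
    )
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc_type = np.where(
        which == "type", signs * rng.uniform(*config.lfc_type_range, size=n), 0.0
    )
    lfc_par = np.where(
        which == "parity", signs * rng.uniform(*config.lfc_parity_range, size=n), 0.0
    )
    lfc_int = np.where(
        which == "interaction",
        signs * rng.uniform(*config.lfc_interaction_range, size=n),
        0.0,
    )
    return pd.DataFrame(
        {
            "de_effect": which,
            "lfc_type": lfc_type,
            "lfc_parity": lfc_par,
            "lfc_interaction": lfc_int,
        }
    )


def simulate_counts(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix under the paired milk-type x parity design.

    count(t, s) ~ NB(mean = L_s * q_t * 2^(x_s' beta_t), dispersion phi)
    with log-normal library factors L_s and baseline abundances q_t.  If
    ``truth`` (from :func:`simulate_annotation`) is given, its transcripts
    are used, forced presence/abundance failures are applied, and the
    returned truth table carries the DE columns; otherwise
    ``config.n_transcripts`` standalone transcripts are simulated.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    if truth is not None:
        tids = list(truth.index)
    else:
        n = config.n_transcripts or 2000
        tids = [f"tx{i:05d}" for i in range(n)]
        truth = pd.DataFrame(index=pd.Index(tids, name="transcript_id"))
    n = len(tids)

    sheet = make_sample_sheet(config.dams_per_parity)
    n_samples = len(sheet)
    de = _plant_de_effects(config, n, rng)
    de.index = pd.Index(tids, name="transcript_id")

    # design columns
    is_milk = (sheet["milk_type"] == "milk").to_numpy(dtype=float)
    not_p1 = (sheet["parity"] > 1).to_numpy(dtype=float)

    # log2 effect per (transcript, sample): parity and interaction effects
    # contrast parities 2-4 against parity 1
    effect = (
        np.outer(de["lfc_type"], is_milk)
        + np.outer(de["lfc_parity"], not_p1)
        + np.outer(de["lfc_interaction"], is_milk * not_p1)
    )

    q = rng.lognormal(mean=np.log(30.0), sigma=config.baseline_sigma, size=n)
    q = np.maximum(q, config.baseline_floor)
    q *= config.mean_total_fragments / q.sum()
    lib = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_samples)

    mu = q[:, None] * lib[None, :] * np.power(2.0, effect)
    phi = config.dispersion
    if phi > 0:
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    else:
        counts = rng.poisson(mu)

    cat = truth["category"] if "category" in truth else pd.Series("", index=truth.index)
    for i, tid in enumerate(tids):
        if cat.loc[tid] == "presence_fail":
            counts[i, :] = 0
            counts[i, int(rng.integers(n_samples))] = 7
        elif cat.loc[tid] == "abundance_fail":
            counts[i, :] = 0
            j1, j2 = rng.choice(n_samples, size=2, replace=False)
            counts[i, j1] = 1
            counts[i, j2] = 1

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                     columns=sheet["sample_id"].tolist()),
        sheet,
    )
    truth_out = truth.join(de)
    return cm, truth_out


def gene_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-gene any-transcript DE truth (requires gene_id and DE columns)."""
    grp = truth.groupby("gene_id")
    return pd.DataFrame(
        {
            "any_type": grp.apply(lambda g: bool((g["lfc_type"] != 0).any())),
            "any_parity": grp.apply(lambda g: bool((g["lfc_parity"] != 0).any())),
            "any_interaction": grp.apply(
                lambda g: bool((g["lfc_interaction"] != 0).any())
            ),
        }
    )


# ---------------------------------------------------------------------------
# bundle


def write_fixture_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write a complete fixture bundle.

    Emits reference.gtf, queries.gtf, transcripts.fa, counts.tsv,
    samples.tsv, evidence.tsv, truth.tsv and config.yaml; all files
    round-trip through the package readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref, queries, truth = simulate_annotation(config, rng)
    seqs, truth = simulate_sequences(queries, truth, config, rng)
    evidence = simulate_evidence(truth, config.evidence_agreement, rng)
    cm, truth = simulate_counts(config, truth, rng)

    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "query_gtf": outdir / "queries.gtf",
        "fasta": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "evidence": outdir / "evidence.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_gtf(ref, paths["reference_gtf"])
    write_gtf(queries, paths["query_gtf"])
    write_fasta(seqs, paths["fasta"])
    cm.to_tsv(paths["counts"], paths["samples"])
    write_evidence_tsv(evidence, paths["evidence"])
    truth.to_csv(paths["truth"], sep="\t")
    config.to_yaml(paths["config"])
    return paths
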