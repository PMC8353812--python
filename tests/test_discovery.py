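"""Discovery cascade: filters, ORF finder, consensus call, full pipeline."""

import numpy as np
import pandas as pd
import pytest

from lactoseq.counts import (
    CountMatrix,
    abundance_filter,
    compute_fpkm,
    presence_filter,
)
from lactoseq.discovery import (
    CodingEvidence,
    consensus_coding_call,
    discovery_pipeline,
    find_longest_orf,
    structural_filter,
)
from lactoseq.intervals import GenomicInterval, TranscriptModel


def _cm(counts, n_parity=1):
    counts = pd.DataFrame(counts)
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    sheet = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "dam_id": [f"d{i // 2}" for i in range(counts.shape[1])],
            "milk_type": ["colostrum", "milk"] * (counts.shape[1] // 2),
            "parity": [1] * counts.shape[1],
        }
    )
    return CountMatrix(counts, sheet)


class TestPresenceAndAbundance:
    def test_presence_rules(self):
        cm = _cm(
            pd.DataFrame(
                {"s0": [0, 5, 3], "s1": [0, 0, 1]},
                index=["zero", "one_sample", "two_samples"],
            )
        )
        assert presence_filter(cm) == {"two_samples"}

    def test_fpkm_formula(self):
        cm = _cm(pd.DataFrame({"s0": [100], "s1": [0]}, index=["t"]))
        fpkm = compute_fpkm(cm, {"t": 2000}, {"s0": 1_000_000, "s1": 1_000_000})
        assert fpkm.loc["t", "s0"] == pytest.approx(50.0)
        assert fpkm.loc["t", "s1"] == 0.0

    def test_fpkm_random_matrix_matches_per_cell_formula(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(6, 4)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(4)],
        )
        cm = _cm(counts)
        lengths = {f"t{i}": int(rng.integers(200, 5000)) for i in range(6)}
        totals = {f"s{i}": float(rng.integers(10**5, 10**6)) for i in range(4)}
        fpkm = compute_fpkm(cm, lengths, totals)
        for t in counts.index:
            for s in counts.columns:
                expected = counts.loc[t, s] / (
                    (lengths[t] / 1000) * (totals[s] / 1e6)
                )
                assert fpkm.loc[t, s] == pytest.approx(expected)

    def test_fpkm_rejects_bad_lengths_and_totals(self):
        cm = _cm(pd.DataFrame({"s0": [1], "s1": [1]}, index=["t"]))
        with pytest.raises(ValueError):
            compute_fpkm(cm, {"t": 0}, None)
        with pytest.raises(ValueError):
            compute_fpkm(cm, {"t": 100}, {"s0": 0.0, "s1": 1.0})

    def test_abundance_boundary(self):
        fpkm = pd.DataFrame(
            {"s0": [0.2, 0.3, 0.0], "s1": [0.2, 0.1, 0.0]},
            index=["below", "at", "zero"],
        )
        assert abundance_filter(fpkm, tau=0.3) == {"at"}

    def test_count_scaling_leaves_fpkm_unchanged(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.integers(0, 300, size=(5, 4)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(4)],
        )
        lengths = {f"t{i}": 1000 for i in range(5)}
        f1 = compute_fpkm(_cm(counts), lengths)
        f2 = compute_fpkm(_cm(counts * 7), lengths)
        pd.testing.assert_frame_equal(f1, f2)


class TestStructuralFilter:
    def test_short_two_exon_fails(self):
        t = TranscriptModel(
            "t", "g", "c", "+",
            [GenomicInterval("c", 1, 100), GenomicInterval("c", 201, 299)],
        )
        ok, why = structural_filter(t)
        assert not ok and why.startswith("length")

    def test_long_single_exon_fails(self):
        t = TranscriptModel("t", "g", "c", "+", [GenomicInterval("c", 1, 5000)])
        ok, why = structural_filter(t)
        assert not ok and why == "single_exon"

    def test_two_exons_250bp_passes(self):
        t = TranscriptModel(
            "t", "g", "c", "+",
            [GenomicInterval("c", 1, 125), GenomicInterval("c", 201, 325)],
        )
        assert structural_filter(t) == (True, "")


def oracle_longest_orf(seq):
    """Brute-force enumeration: every ATG, scan codons to the first stop."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                aa = (j - i) // 3
                if best is None or aa > best:
                    best = aa
                break
            j += 3
    return best


class TestFindLongestOrf:
    def test_no_atg_absent(self):
        assert find_longest_orf("CCGTTCGGTT") is None

    def test_120_aa_orf(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(list("CGT"), size=3 * 119))
        seq = "CCT" + "ATG" + body + "TAA" + "CGC"
        assert find_longest_orf(seq) == 120

    def test_matches_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 400))))
            assert find_longest_orf(seq) == oracle_longest_orf(seq)

    def test_six_frame_finds_reverse_orf(self):
        rng = np.random.default_rng(1)
        body = "".join(rng.choice(list("CGT"), size=3 * 50))
        fwd = "ATG" + body + "TGA"
        comp = str.maketrans("ACGT", "TGCA")
        rc = fwd.translate(comp)[::-1]
        assert find_longest_orf(rc) is None or find_longest_orf(rc) < 51
        assert find_longest_orf(rc, six_frame=True) == 51

    def test_empty_and_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            find_longest_orf("")
        with pytest.raises(ValueError):
            find_longest_orf("ACGU")


class TestConsensusCodingCall:
    def test_long_orf_decides_coding(self):
        ev = CodingEvidence("t", 130, "noncoding", -1.0, -1.0, None)
        assert consensus_coding_call(ev) == "coding"

    def test_all_negative_is_noncoding(self):
        ev = CodingEvidence("t", 50, "noncoding", -1.0, -0.5, None)
        assert consensus_coding_call(ev) == "noncoding"

    def test_disagreement_is_ambiguous(self):
        ev = CodingEvidence("t", 50, "coding", -1.0, 0.4, None)
        assert consensus_coding_call(ev) == "ambiguous"

    def test_pfam_hit_decides_coding(self):
        ev = CodingEvidence("t", 50, "noncoding", -1.0, -1.0, 0.5)
        assert consensus_coding_call(ev) == "coding"

    def test_zero_scores_are_ambiguous(self):
        ev = CodingEvidence("t", 50, "coding", 0.0, 1.0, None)
        assert consensus_coding_call(ev) == "ambiguous"

    def test_missing_orf_rejected(self):
        with pytest.raises(ValueError):
            consensus_coding_call(CodingEvidence("t", None))


class TestDiscoveryPipeline:
    def test_verdicts_match_planted_truth(self, small_bundle_parts):
        cfg, ref, queries, truth, seqs, evidence, cm = small_bundle_parts
        verdicts = discovery_pipeline(queries, ref, cm, evidence)
        assert set(verdicts) == set(truth.index)  # classes partition input
        for tid, v in verdicts.items():
            assert v.klass == truth.loc[tid, "expected_class"], tid
            assert v.reason == truth.loc[tid, "reason"], tid
            if v.klass == "novel_lncRNA":
                assert v.lnc_subclass == truth.loc[tid, "lnc_subclass"]

    def test_known_bypasses_structural_filter(self):
        # a '=' transcript failing the structural filter is still "known"
        exon = GenomicInterval("c", 1, 150)
        ref_t = TranscriptModel("r", "g", "c", "+", [exon])
        q = TranscriptModel("q", "gq", "c", "+", [exon])  # single exon, 150 bp
        from lactoseq.annotation import ReferenceAnnotation

        counts = pd.DataFrame({"s0": [10], "s1": [10]}, index=["q"])
        verdicts = discovery_pipeline([q], ReferenceAnnotation([ref_t]), _cm(counts), {})
        assert verdicts["q"].klass == "known"

    def test_single_sample_discarded_with_presence_reason(self):
        q = TranscriptModel(
            "q", "g", "c", "+",
            [GenomicInterval("c", 1, 150), GenomicInterval("c", 301, 450)],
        )
        from lactoseq.annotation import ReferenceAnnotation

        counts = pd.DataFrame({"s0": [10, 50], "s1": [0, 60]}, index=["q", "filler"])
        verdicts = discovery_pipeline([q], ReferenceAnnotation([]), _cm(counts), {})
        assert verdicts["q"].klass == "discarded"
        assert verdicts["q"].reason == "presence"

    def test_id_mismatch_lists_missing(self, small_bundle_parts):
        cfg, ref, queries, truth, seqs, evidence, cm = small_bundle_parts
        cm2 = CountMatrix(cm.counts.iloc[5:], cm.samples)
        with pytest.raises(KeyError, match="MSTRG"):
            discovery_pipeline(queries, ref, cm2, evidence)

    def test_threshold_monotonicity(self, small_bundle_parts):
        """Raising tau or the length threshold never adds kept transcripts."""
        cfg, ref, queries, truth, seqs, evidence, cm = small_bundle_parts

        def kept(**kw):
            v = discovery_pipeline(queries, ref, cm, evidence, **kw)
            return {t for t, r in v.items() if r.klass != "discarded"}

        base = kept()
        assert kept(min_fpkm=1.0) <= base
        assert kept(min_length=400) <= base
        assert kept(min_orf_aa=200) <= base
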