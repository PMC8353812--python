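"""Normalization, dispersion, NB GLM tests, BH and the DET partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lactoseq.counts import CountMatrix
from lactoseq.de import (
    DetThresholds,
    MilkDEModel,
    base_mean,
    bh_adjust,
    design_matrices,
    det_partition,
    estimate_dispersion,
    expression_summary,
    nb_glm_test,
    size_factors,
)
from lactoseq.simulate import SimulationConfig, make_sample_sheet, simulate_counts


def _sheet(n, parities=(1,)):
    rows = []
    i = 0
    for p in parities:
        for _ in range(n // (2 * len(parities))):
            rows.append((f"s{i}", f"d{i // 2}", "colostrum", p))
            rows.append((f"s{i + 1}", f"d{i // 2}", "milk", p))
            i += 2
    return pd.DataFrame(rows, columns=["sample_id", "dam_id", "milk_type", "parity"])


def _matrix(values, index=None):
    df = pd.DataFrame(values)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    if index is not None:
        df.index = index
    return CountMatrix(df, _sheet(df.shape[1]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _matrix({"s0": [10, 20, 5], "s1": [10, 20, 5]})
        assert np.allclose(size_factors(cm), 1.0)

    def test_hand_median_of_ratios(self):
        cm = _matrix([[10, 20], [30, 60]])
        sf = size_factors(cm)
        assert sf.iloc[0] == pytest.approx(0.7071, abs=1e-4)
        assert sf.iloc[1] == pytest.approx(1.4142, abs=1e-4)

    def test_column_scale_equivariance(self):
        # size factors are defined up to a common constant (they enter the
        # GLM only through offsets), so scaling one library by c must scale
        # its factor by c relative to every other sample
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 200, size=(30, 4))
        sf1 = size_factors(_matrix(counts))
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 5
        sf2 = size_factors(_matrix(scaled))
        for j in (0, 1, 3):
            ratio1 = sf1.iloc[2] / sf1.iloc[j]
            ratio2 = sf2.iloc[2] / sf2.iloc[j]
            assert ratio2 == pytest.approx(5 * ratio1, rel=1e-9)

    def test_no_all_positive_row_raises_with_fallback_advice(self):
        cm = _matrix([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(cm)
        sf = size_factors(cm, pseudo_reference=True)
        assert (sf > 0).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 4)),
            index=[f"t{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(4)],
        )
        sheet = _sheet(4)
        sf1 = size_factors(CountMatrix(counts, sheet))
        sf2 = size_factors(CountMatrix(counts.iloc[::-1], sheet))
        pd.testing.assert_series_equal(sf1, sf2)


class TestBaseMean:
    def test_zero_row_and_unit_factors(self):
        cm = _matrix([[0, 0], [4, 6]])
        sf = pd.Series([1.0, 1.0], index=cm.counts.columns)
        bm = base_mean(cm, sf)
        assert bm.iloc[0] == 0.0
        assert bm.iloc[1] == pytest.approx(5.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        cm = _matrix(rng.integers(1, 500, size=(5, 4)))
        sf = size_factors(cm)
        bm = base_mean(cm, sf)
        manual = (cm.counts / sf).mean(axis=1)
        assert np.allclose(bm, manual)


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(11)
        sheet = make_sample_sheet((8, 8, 8, 8))  # 64 dams -> 128 samples
        counts = pd.DataFrame(
            rng.poisson(500.0, size=(300, len(sheet))),
            index=[f"t{i}" for i in range(300)],
            columns=sheet["sample_id"],
        )
        cm = CountMatrix(counts, sheet)
        disp = estimate_dispersion(cm, size_factors(cm))
        assert abs(float(disp.median())) < 0.05

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(13)
        sheet = make_sample_sheet((17, 16, 16, 16))  # 130 samples
        phi, mu = 0.5, 200.0
        counts = pd.DataFrame(
            rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=(200, len(sheet))),
            index=[f"t{i}" for i in range(200)],
            columns=sheet["sample_id"],
        )
        cm = CountMatrix(counts, sheet)
        disp = estimate_dispersion(cm, size_factors(cm, pseudo_reference=True))
        assert 0.35 <= float(disp.median()) <= 0.65

    def test_constant_counts_floored_at_zero(self):
        cm = _matrix([[5, 5, 5, 5], [9, 9, 9, 9]])
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = estimate_dispersion(cm, sf)
        assert (disp <= 1e-8).all()


class TestNbGlmTest:
    def test_recovers_planted_type_effect(self):
        rng = np.random.default_rng(4)
        sheet = make_sample_sheet((3, 3, 2, 2))  # 10 dams -> 10 per milk type
        designs = design_matrices(sheet)
        is_milk = (sheet["milk_type"] == "milk").to_numpy()
        phi, mu0, lfc = 0.05, 300.0, 3.0
        mu = mu0 * np.power(2.0, lfc * is_milk)
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        res = nb_glm_test(y, designs, np.ones(len(sheet)), phi)
        assert res["p_type"] < 1e-4
        assert abs(res["log2fc_type"] - lfc) < 0.5

    def test_all_zero_row_rejected(self):
        sheet = make_sample_sheet((1, 1, 1, 1))
        designs = design_matrices(sheet)
        with pytest.raises(ValueError):
            nb_glm_test(np.zeros(len(sheet)), designs, np.ones(len(sheet)), 0.1)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        sheet = make_sample_sheet((2, 2, 2, 2))
        y = rng.negative_binomial(2, 0.01, size=len(sheet)).astype(float)
        designs = design_matrices(sheet)
        res1 = nb_glm_test(y, designs, np.ones(len(sheet)), 0.3)
        perm = rng.permutation(len(sheet))
        sheet2 = sheet.iloc[perm].reset_index(drop=True)
        res2 = nb_glm_test(y[perm], design_matrices(sheet2), np.ones(len(sheet)), 0.3)
        for k in ("p_interaction", "p_type", "p_parity", "log2fc_type"):
            assert res1[k] == pytest.approx(res2[k], rel=1e-6, abs=1e-10)


class TestNullCalibration:
    def test_all_three_tests_near_nominal(self):
        """Null transcripts reject at 0.05 within 2x binomial MC error."""
        cfg = SimulationConfig(
            seed=33,
            n_transcripts=700,
            dams_per_parity=(3, 3, 3, 3),
            dispersion=0.3,
            de_frac_type=0.0,
            de_frac_parity=0.0,
            de_frac_interaction=0.0,
        )
        cm, truth = simulate_counts(cfg)
        res = MilkDEModel(cm).fit()
        tx = res.transcripts
        band = 2 * np.sqrt(0.05 * 0.95 / len(tx))
        for eff in ("type", "parity", "interaction"):
            rate = float((tx[f"p_{eff}"] <= 0.05).mean())
            assert abs(rate - 0.05) <= band, (eff, rate)


def oracle_bh(p):
    """Step-up definition: sorted p * m / rank, running min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_nan_passthrough_and_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        # m = 2 tested entries
        assert adj[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        assert np.allclose(bh_adjust(ps), oracle_bh(ps))
        assert (bh_adjust(ps) >= np.asarray(ps) - 1e-12).all()


class TestDetPartition:
    def _frame(self, **rows):
        df = pd.DataFrame(rows).T
        df.columns = ["fdr_interaction", "fdr_type", "fdr_parity", "log2fc_type"]
        return df

    def test_partition_rules(self):
        df = self._frame(
            inter_only=[0.005, 0.001, 0.001, 5.0],
            small_lfc=[0.5, 0.005, 0.5, 1.5],
            type_hit=[0.5, 0.005, 0.5, 2.5],
            parity_hit=[0.5, 0.5, 0.005, 0.0],
        )
        det = det_partition(df, DetThresholds())
        assert det["interaction"] == {"inter_only"}
        assert det["type"] == {"type_hit"}
        assert det["parity"] == {"parity_hit"}

    def test_sets_disjoint_from_interaction(self, de_fixture):
        _, cm, _ = de_fixture
        res = MilkDEModel(cm).fit(bartlett=False)
        det = res.det_sets()
        assert not det["interaction"] & det["type"]
        assert not det["interaction"] & det["parity"]


class TestExpressionSummary:
    def test_single_gene_rank_one(self):
        cm = _matrix([[5, 10]], index=["g1"])
        sf = pd.Series([1.0, 1.0], index=cm.counts.columns)
        summ = expression_summary(cm, sf, {"a": ["s0"], "b": ["s1"]})
        assert summ.loc["g1", "rank_a"] == 1 and summ.loc["g1", "rank_b"] == 1

    def test_ties_broken_by_id(self):
        cm = _matrix([[5, 5], [5, 5]], index=["gB", "gA"])
        sf = pd.Series([1.0, 1.0], index=cm.counts.columns)
        summ = expression_summary(cm, sf, {"all": ["s0", "s1"]})
        assert summ.loc["gA", "rank_all"] == 1
        assert summ.loc["gB", "rank_all"] == 2

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(10)
        cm = _matrix(rng.integers(0, 100, size=(8, 4)), index=[f"g{i}" for i in range(8)])
        sf = size_factors(cm, pseudo_reference=True)
        groups = {"c": ["s0", "s1"], "m": ["s2", "s3"]}
        summ = expression_summary(cm, sf, groups)
        norm = cm.counts / sf
        for g, ss in groups.items():
            assert np.allclose(summ[f"mean_{g}"], norm[ss].mean(axis=1))

    def test_groups_must_partition(self):
        cm = _matrix([[1, 2]])
        sf = pd.Series([1.0, 1.0], index=cm.counts.columns)
        with pytest.raises(ValueError):
            expression_summary(cm, sf, {"a": ["s0"]})
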