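import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboprof.difftrans import (bh_fdr, call_dtgs, condition_concordance,
                                log2_te_change, permutation_p_value)
from riboprof.difftrans import test_differential_te as diff_te_test
from riboprof.errors import ConfigurationError
from riboprof.quant import TETable


def _te_table(values: dict[str, list[float]]) -> TETable:
    """values: gene_id -> per-sample log2 TE."""
    rows = []
    for gene, reps in values.items():
        for i, v in enumerate(reps):
            rows.append({"gene_id": gene, "sample": f"s{i}", "rpkm_fp": 2.0 ** v,
                         "rpkm_mrna": 1.0, "te": 2.0 ** v, "log2_te": v})
    return TETable(table=pd.DataFrame(rows))


class TestLog2TEChange:
    def test_equal_te_gives_zero(self):
        t = _te_table({"a": [1.0, 1.0], "b": [0.5, 0.5]})
        out = log2_te_change(t, t)
        assert (out["log2_te_change"] == 0).all()

    def test_ratio_15_gives_0585(self):
        t = _te_table({"a": [np.log2(1.5)]})
        c = _te_table({"a": [0.0]})
        out = log2_te_change(t, c)
        assert out["log2_te_change"].iloc[0] == pytest.approx(0.585, abs=5e-4)

    def test_ratio_half_gives_minus_one(self):
        t = _te_table({"a": [-1.0]})
        c = _te_table({"a": [0.0]})
        assert log2_te_change(t, c)["log2_te_change"].iloc[0] == pytest.approx(-1.0)

    def test_disjoint_gene_sets_error(self):
        with pytest.raises(ConfigurationError):
            log2_te_change(_te_table({"a": [1.0]}), _te_table({"b": [1.0]}))

    def test_label_swap_negates(self):
        t = _te_table({"a": [1.0, 1.2], "b": [0.0, 0.1]})
        c = _te_table({"a": [0.3, 0.2], "b": [0.4, 0.5]})
        fwd = log2_te_change(t, c).set_index("gene_id")["log2_te_change"]
        rev = log2_te_change(c, t).set_index("gene_id")["log2_te_change"]
        np.testing.assert_allclose(fwd, -rev)


class TestPerGeneTest:
    def test_identical_replicates_p_one(self):
        t = _te_table({"a": [1.0, 1.0, 1.0]})
        out = diff_te_test(t, t)
        assert out["p_value"].iloc[0] == 1.0

    def test_zero_variance_different_means_untestable(self):
        t = _te_table({"a": [2.0, 2.0, 2.0]})
        c = _te_table({"a": [0.0, 0.0, 0.0]})
        out = diff_te_test(t, c)
        assert not out["testable"].iloc[0]

    def test_strong_separation_small_p(self):
        t = _te_table({"a": [3.0, 3.1, 2.9]})
        c = _te_table({"a": [0.0, 0.0, 0.0]})
        out = diff_te_test(t, c)
        assert out["p_value"].iloc[0] < 0.01
        # the exact permutation oracle agrees the split is the most extreme
        perm = permutation_p_value(np.array([3.0, 3.1, 2.9]), np.zeros(3))
        assert perm == pytest.approx(2 / 20)  # both tail assignments

    def test_single_replicate_untestable(self):
        t = _te_table({"a": [1.0]})
        c = _te_table({"a": [0.0]})
        out = diff_te_test(t, c)
        assert not out["testable"].any()

    def test_permutation_matches_manual_enumeration(self, rng):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        p = permutation_p_value(a, b)
        assert 0 < p <= 1
        # minimum possible two-sided p over C(6,3)=20 assignments is 2/20
        assert p >= 2 / 20 - 1e-12

    def test_welch_type_one_calibration(self):
        gen = np.random.default_rng(1234)
        n_genes = 2000
        xt = gen.normal(size=(n_genes, 3))
        xc = gen.normal(size=(n_genes, 3))
        t = TETable(table=pd.DataFrame({
            "gene_id": np.repeat([f"g{i}" for i in range(n_genes)], 3),
            "sample": np.tile(["s0", "s1", "s2"], n_genes),
            "rpkm_fp": 1.0, "rpkm_mrna": 1.0, "te": 1.0,
            "log2_te": xt.ravel()}))
        c = TETable(table=t.table.assign(log2_te=xc.ravel()))
        out = diff_te_test(t, c)
        frac = (out["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)


class TestBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_all_ties(self):
        np.testing.assert_allclose(bh_fdr([0.03] * 10), [0.03] * 10)

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ConfigurationError):
                bh_fdr(bad)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1, size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sorted_order(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()


class TestCallDTGs:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2_te_change",
                                           "p_value", "q_value"])

    def test_all_criteria_met_up(self):
        rec = self._records([("a", np.log2(1.6), 0.01, 0.01)])
        called, summary = call_dtgs(rec)
        assert called["call"].iloc[0] == "up"
        assert summary["n_up"] == 1

    def test_fdr_failure_blocks_call(self):
        rec = self._records([("a", np.log2(1.6), 0.01, 0.2)])
        called, _ = call_dtgs(rec)
        assert called["call"].iloc[0] == "unchanged"

    def test_down_call_symmetric(self):
        rec = self._records([("a", np.log2(0.5), 0.01, 0.01)])
        called, summary = call_dtgs(rec)
        assert called["call"].iloc[0] == "down"
        assert summary["n_down"] == 1

    def test_ratio_inside_band_unchanged(self):
        rec = self._records([("a", np.log2(1.2), 0.001, 0.001)])
        called, _ = call_dtgs(rec)
        assert called["call"].iloc[0] == "unchanged"

    def test_threshold_validation(self):
        rec = self._records([("a", 0.0, 0.5, 0.5)])
        with pytest.raises(ConfigurationError):
            call_dtgs(rec, lower=2.0, upper=1.5)
        with pytest.raises(ConfigurationError):
            call_dtgs(rec, alpha=0.0)

    def test_idempotent_and_order_invariant(self, rng):
        rows = [(f"g{i}", float(rng.normal()), float(rng.uniform(1e-4, 1)),
                 float(rng.uniform(1e-4, 1))) for i in range(50)]
        rec = self._records(rows)
        called1, s1 = call_dtgs(rec)
        called2, s2 = call_dtgs(called1[["gene_id", "log2_te_change",
                                         "p_value", "q_value"]])
        assert s1 == s2
        shuffled = rec.sample(frac=1.0, random_state=0)
        _, s3 = call_dtgs(shuffled)
        assert s1 == s3

    def test_label_swap_swaps_counts(self, rng):
        rows = [(f"g{i}", float(rng.normal(0, 1.2)),
                 float(rng.uniform(1e-4, 0.04)), float(rng.uniform(1e-4, 0.04)))
                for i in range(100)]
        rec = self._records(rows)
        # exact swap symmetry needs reciprocal ratio bounds; the default
        # 0.667 is the printed rounding of 1/1.5 and is not an exact
        # reciprocal, so a gene in the sliver between them could flip
        _, fwd = call_dtgs(rec, lower=1 / 1.5, upper=1.5)
        rec_swapped = rec.assign(log2_te_change=-rec["log2_te_change"])
        _, rev = call_dtgs(rec_swapped, lower=1 / 1.5, upper=1.5)
        assert fwd["n_up"] == rev["n_down"]
        assert fwd["n_down"] == rev["n_up"]


class TestConcordance:
    def test_identity(self, rng):
        x = rng.normal(size=100)
        assert condition_concordance(x, x) == pytest.approx(1.0)

    def test_sign_insensitive(self, rng):
        x = rng.normal(size=100)
        assert condition_concordance(x, -2 * x) == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ConfigurationError):
            condition_concordance([1, 2, 3], [5, 5, 5])

    def test_too_few_genes(self):
        with pytest.raises(ConfigurationError):
            condition_concordance([1, 2], [1, 2])

    def test_noise_matches_closed_form(self):
        gen = np.random.default_rng(77)
        x = gen.normal(0, 1, size=2000)
        sigma = 0.5
        y = x + gen.normal(0, sigma, size=2000)
        expected = np.var(x) / (np.var(x) + sigma ** 2)
        assert condition_concordance(x, y) == pytest.approx(expected, abs=0.05)
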