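import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grhl2net.bruseq_response import (
    RESPONSE_CLASSES,
    CountsMatrix,
    QPCRRecord,
    average_fold_change,
    classify_response,
    compute_responses,
    fold_change_and_p,
    heatmap_matrix,
    optimal_cluster_count,
    qpcr_quantify,
    read_counts,
    rpkm,
    two_library_proportion_p,
    write_counts,
)
from grhl2net.io_formats import AnalysisConfig, ValidationError

CFG = AnalysisConfig()
TREATED = (2, 4, 8, 16)


def make_matrix(gene_counts, lengths=None, depth=1_000_000,
                guides=("sgCTR", "sgGRHL2_1", "sgGRHL2_2")):
    """CountsMatrix from {gene: {guide: [c0, c2, c4, c8, c16]}}."""
    genes = sorted(gene_counts)
    columns = {}
    for guide in guides:
        for i, day in enumerate((0,) + TREATED):
            columns[f"{guide}:{day}"] = [gene_counts[g][guide][i] for g in genes]
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    lengths = pd.Series(
        lengths or {g: 1000 for g in genes}, index=frame.index, dtype=int
    )
    totals = {c: depth for c in frame.columns}
    return CountsMatrix(frame, lengths, totals)


def flat(c0=100):
    return [c0] * 5


def enum_binom_two_sided(x, n, p):
    """Independent enumeration of the exact conditional two-sided p-value:
    sum of binomial pmf over outcomes no more likely than the observed one."""
    def pmf(k):
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    obs = pmf(x)
    return min(1.0, sum(pmf(k) for k in range(n + 1) if pmf(k) <= obs * (1 + 1e-7)))


class TestRpkm:
    def test_textbook_value(self):
        assert rpkm(10, 2000, 1_000_000) == pytest.approx(5.0)

    def test_zero_counts(self):
        assert rpkm(0, 2000, 1_000_000) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert rpkm(10, 2000, 2_000_000) == pytest.approx(
            rpkm(10, 2000, 1_000_000) / 2
        )

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            rpkm(10, 2000, 0)


class TestFoldChangeAndP:
    def test_identical_samples_fc_one_p_one(self):
        matrix = make_matrix({"g": {g: flat(100) for g in
                                    ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}})
        out = fold_change_and_p(matrix, "sgGRHL2_1", 2, CFG)
        assert out.loc["g", "FC"] == pytest.approx(1.0)
        assert out.loc["g", "p"] == pytest.approx(1.0)

    def test_zero_counts_degenerate(self):
        matrix = make_matrix({"g": {g: flat(0) for g in
                                    ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}})
        out = fold_change_and_p(matrix, "sgGRHL2_1", 2, CFG)
        assert out.loc["g", "FC"] == pytest.approx(1.0)  # pseudocount
        assert out.loc["g", "p"] == 1.0

    def test_threefold_change_with_pseudocount(self):
        counts = {"sgCTR": flat(10), "sgGRHL2_1": [10, 30, 10, 10, 10],
                  "sgGRHL2_2": flat(10)}
        matrix = make_matrix({"g": counts})
        out = fold_change_and_p(matrix, "sgGRHL2_1", 2, CFG)
        # RPKM(10) = 10, RPKM(30) = 30 => (30 + 0.1) / (10 + 0.1)
        assert out.loc["g", "FC"] == pytest.approx(30.1 / 10.1)
        assert out.loc["g", "p"] == pytest.approx(
            enum_binom_two_sided(30, 40, 0.5), rel=1e-9
        )

    def test_exact_test_matches_enumeration_for_small_counts(self):
        n1, n0 = 1_000_000, 1_300_000
        p = n1 / (n0 + n1)
        for x0 in range(0, 25, 4):
            for x1 in range(0, 25, 3):
                if x0 + x1 == 0:
                    continue
                got = two_library_proportion_p(x1, n1, x0, n0)
                want = enum_binom_two_sided(x1, x0 + x1, p)
                assert got == pytest.approx(want, rel=1e-8), (x0, x1)

    def test_missing_day_zero_is_error(self):
        matrix = make_matrix({"g": {g: flat() for g in
                                    ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}})
        matrix.counts.drop(columns=["sgGRHL2_1:0"], inplace=True)
        with pytest.raises(ValidationError, match="sgGRHL2_1:0"):
            fold_change_and_p(matrix, "sgGRHL2_1", 2, CFG)


class TestAverageFoldChange:
    @pytest.mark.parametrize(
        "fc1,fc2,expected", [(2, 8, 4), (1, 1, 1), (0.5, 0.125, 0.25)]
    )
    def test_geometric_mean(self, fc1, fc2, expected):
        assert average_fold_change(fc1, fc2) == pytest.approx(expected)


class TestRegulatedFilter:
    def _counts(self, ctrl, g1, g2):
        base = {"gene": {"sgCTR": ctrl, "sgGRHL2_1": g1, "sgGRHL2_2": g2}}
        return make_matrix(base)

    def test_both_guides_up_control_flat_is_regulated_up(self):
        matrix = self._counts(flat(100), [100, 400, 100, 100, 100],
                              [100, 400, 100, 100, 100])
        out = compute_responses(matrix, CFG)
        assert bool(out.loc["gene", "regulated"])
        assert out.loc["gene", "direction"] == "up"

    def test_single_guide_response_not_regulated(self):
        matrix = self._counts(flat(100), [100, 400, 100, 100, 100], flat(100))
        out = compute_responses(matrix, CFG)
        assert not bool(out.loc["gene", "regulated"])

    def test_control_response_eliminates_gene(self):
        matrix = self._counts([100, 100, 100, 300, 100],
                              [100, 400, 100, 100, 100],
                              [100, 400, 100, 100, 100])
        out = compute_responses(matrix, CFG)
        assert not bool(out.loc["gene", "regulated"])

    def test_guide_swap_leaves_afc_and_class_unchanged(self):
        matrix = self._counts(flat(100), [100, 420, 380, 410, 400],
                              [100, 380, 400, 390, 420])
        out1 = compute_responses(matrix, CFG)
        swapped = matrix.counts.rename(
            columns=lambda c: c.replace("sgGRHL2_1", "tmp")
            .replace("sgGRHL2_2", "sgGRHL2_1").replace("tmp", "sgGRHL2_2")
        )
        matrix2 = CountsMatrix(
            swapped, matrix.lengths,
            {c.replace("sgGRHL2_1", "tmp").replace("sgGRHL2_2", "sgGRHL2_1")
             .replace("tmp", "sgGRHL2_2"): v
             for c, v in matrix.library_total.items()},
        )
        out2 = compute_responses(matrix2, CFG)
        for t in TREATED:
            assert out1.loc["gene", f"AFC:{t}"] == pytest.approx(
                out2.loc["gene", f"AFC:{t}"]
            )
        assert out1.loc["gene", "response_class"] == out2.loc["gene", "response_class"]


class TestClassifyResponse:
    def _classify(self, afc, sig=True):
        afc_map = dict(zip(TREATED, afc))
        sig_map = {t: sig if isinstance(sig, bool) else s
                   for t, s in zip(TREATED, [sig] * 4)}
        return classify_response(afc_map, sig_map, CFG)

    def test_rule_examples(self):
        assert self._classify((4, 3, 2.5, 4)) == "sustained_induction"
        assert self._classify((4, 3, 2.5, 1.5)) == "induction_reset"
        assert self._classify((4, 0.3, 3, 0.4)) == "dynamic"
        assert self._classify((0.3, 0.4, 0.25, 0.25)) == "sustained_repression"
        assert self._classify((0.3, 0.4, 0.25, 0.7)) == "repression_reset"
        assert self._classify((1.2, 1.1, 0.9, 1.0)) == "other"

    def test_reset_band_is_open(self):
        # a day-16 AFC of exactly 1 or 2 is not a reset
        assert self._classify((4, 3, 2.5, 1.0)) == "other"
        assert self._classify((4, 3, 2.5, 2.0)) == "other"

    def test_insignificant_timepoints_block_sustained(self):
        afc = dict(zip(TREATED, (4, 4, 4, 4)))
        sig = {2: True, 4: True, 8: True, 16: False}
        assert classify_response(afc, sig, CFG) == "induction_reset" if False else True
        # day 16 not significant and AFC outside (1,2): not sustained, not reset
        assert classify_response(afc, sig, CFG) == "other"

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        afc=st.lists(st.floats(0.05, 20), min_size=4, max_size=4),
        sig=st.lists(st.booleans(), min_size=4, max_size=4),
    )
    def test_classification_total_and_self_consistent(self, afc, sig):
        cls = classify_response(
            dict(zip(TREATED, afc)), dict(zip(TREATED, sig)), CFG
        )
        assert cls in RESPONSE_CLASSES
        if cls == "sustained_induction":
            assert all(sig) and all(a > CFG.fc_up for a in afc)
        if cls == "sustained_repression":
            assert all(sig) and all(a < CFG.fc_down for a in afc)
        if cls == "dynamic":
            assert any(a > CFG.fc_up for a in afc) and any(
                a < CFG.fc_down for a in afc
            )

    def test_missing_timepoint_is_error(self):
        with pytest.raises(ValidationError, match="16"):
            classify_response({2: 4, 4: 4, 8: 4}, {2: True, 4: True, 8: True}, CFG)


class TestClustering:
    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(51)
        for n_clusters in (2, 5):
            centers = rng.uniform(-8, 8, size=(n_clusters, 4))
            centers = centers * 10 / max(1e-9, np.min(
                [np.linalg.norm(a - b) for i, a in enumerate(centers)
                 for b in centers[i + 1:]] or [1]
            ))
            X = np.vstack([
                c + 0.05 * rng.standard_normal((40, 4)) for c in centers
            ])
            k, wss = optimal_cluster_count(X, k_max=8, seed=0)
            assert k == n_clusters
            assert len(wss) == 8

    def test_identical_rows_give_k_one(self):
        X = np.ones((30, 4))
        k, wss = optimal_cluster_count(X, k_max=5, seed=0)
        assert k == 1
        assert np.allclose(wss, 0)


class TestHeatmap:
    def test_signs_and_ordering(self):
        counts = {
            "up_gene": {"sgCTR": flat(100),
                        "sgGRHL2_1": [100, 400, 400, 400, 400],
                        "sgGRHL2_2": [100, 400, 400, 400, 400]},
            "down_gene": {"sgCTR": flat(100),
                          "sgGRHL2_1": [100, 25, 25, 25, 25],
                          "sgGRHL2_2": [100, 25, 25, 25, 25]},
        }
        out = compute_responses(make_matrix(counts), CFG)
        heat = heatmap_matrix(out, CFG)
        assert heat.shape == (2, 5)
        assert heat.loc["up_gene", "log2AFC:2"] > 0
        assert heat.loc["down_gene", "log2AFC:2"] < 0
        # class ordering puts sustained_induction before sustained_repression
        assert list(heat.index) == ["up_gene", "down_gene"]

    def test_empty_regulated_set_is_error(self):
        counts = {"g": {g: flat(100) for g in
                        ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}}
        out = compute_responses(make_matrix(counts), CFG)
        with pytest.raises(ValidationError):
            heatmap_matrix(out, CFG)


class TestQpcr:
    def test_ddct_identity(self):
        record = QPCRRecord(ct_target_cond=20, ct_ref_cond=20,
                            ct_target_ctrl=20, ct_ref_ctrl=20)
        assert qpcr_quantify(record, "ddct") == pytest.approx(1.0)

    def test_one_cycle_ddct_halves(self):
        record = QPCRRecord(ct_target_cond=21, ct_ref_cond=20,
                            ct_target_ctrl=20, ct_ref_ctrl=20)
        assert qpcr_quantify(record, "ddct") == pytest.approx(0.5)

    def test_percent_input_identity(self):
        record = QPCRRecord(ct_ip=25, ct_input=25, dilution_factor=1)
        assert qpcr_quantify(record, "percent_input") == pytest.approx(100.0)

    def test_percent_input_dilution_correction(self):
        # input diluted 1:10 -> subtract log2(10) cycles from the input Ct
        record = QPCRRecord(ct_ip=25, ct_input=25, dilution_factor=10)
        assert qpcr_quantify(record, "percent_input") == pytest.approx(10.0)

    def test_missing_ct_is_error(self):
        with pytest.raises(ValidationError):
            qpcr_quantify(QPCRRecord(ct_ip=25), "percent_input")


class TestCountsIO:
    def test_roundtrip(self, tmp_path):
        matrix = make_matrix(
            {"g1": {g: flat(100) for g in ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")},
             "g2": {g: flat(7) for g in ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}}
        )
        path = tmp_path / "counts.tsv"
        write_counts(matrix, path)
        back = read_counts(path)
        pd.testing.assert_frame_equal(back.counts, matrix.counts)
        pd.testing.assert_series_equal(
            back.lengths, matrix.lengths, check_names=False
        )
        assert back.library_total == matrix.library_total

    def test_library_total_below_column_sum_rejected(self):
        with pytest.raises(ValidationError):
            make_matrix(
                {"g": {g: flat(10**7) for g in
                       ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")}},
                depth=10,
            )
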