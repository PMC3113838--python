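"""Spot normalization and enrichment classification against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mitomir.enrichment import (
    background_threshold,
    calibrator_normalize,
    classify_enrichment,
    enrich_pipeline,
    filter_spots,
    heatmap_table,
    net_intensity,
    per_array_ratios,
    probe_mean_ratio,
    spot_ratio,
)
from mitomir.synthetic import PlantedTruth, gen_array_scans


def make_scan(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "spot_index": 1,
        "hy5_background": 0.0,
        "hy3_background": 0.0,
        "is_calibrator": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestSpotLevel:
    @pytest.mark.parametrize(
        "signal,background,expected", [(100, 30, 70), (30, 30, 0), (20, 30, -10)]
    )
    def test_net_intensity(self, signal, background, expected):
        scan = make_scan(
            [{"probe_id": "a", "hy5_signal": signal, "hy5_background": background,
              "hy3_signal": 1, "hy3_background": 0}]
        )
        assert net_intensity(scan, "hy5").iloc[0] == expected

    def test_background_threshold_is_median(self):
        scan = make_scan(
            [{"probe_id": f"p{i}", "hy5_signal": 0, "hy5_background": b,
              "hy3_signal": 0, "hy3_background": 0}
             for i, b in enumerate([10, 20, 30, 40])]
        )
        assert background_threshold(scan, "hy5") == 25.0

    def test_background_threshold_matches_sorted_midpoint(self, rng):
        bgs = rng.gamma(5.0, 30.0, size=1000)
        scan = make_scan(
            [{"probe_id": f"p{i}", "hy5_signal": 0, "hy5_background": b,
              "hy3_signal": 0, "hy3_background": 0} for i, b in enumerate(bgs)]
        )
        s = np.sort(bgs)
        oracle = 0.5 * (s[499] + s[500])
        assert background_threshold(scan, "hy5") == pytest.approx(oracle, rel=1e-12)

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            background_threshold(make_scan([]).reindex(columns=[
                "probe_id", "hy5_signal", "hy5_background",
                "hy3_signal", "hy3_background", "is_calibrator"]), "hy5")

    def test_filter_requires_both_channels(self):
        # thresholds are 25/25 (constant backgrounds)
        rows = []
        for i, (n5, n3) in enumerate([(70, 70), (70, 10), (10, 70), (-5, 70)]):
            rows.append({
                "probe_id": f"p{i}", "hy5_signal": 25 + n5, "hy5_background": 25,
                "hy3_signal": 25 + n3, "hy3_background": 25,
            })
        kept = filter_spots(make_scan(rows))
        assert list(kept) == [True, False, False, False]

    def test_filter_matches_brute_force_on_generated_scan(self, small_design):
        truth = PlantedTruth(folds={"p01": 3.0}, noise_cv=0.3, seed=11,
                             abundance_median=300.0)
        (scan,) = gen_array_scans(small_design, truth, n_arrays=1)
        thr5 = np.median(scan["hy5_background"])
        thr3 = np.median(scan["hy3_background"])
        oracle = [
            (r.hy5_signal - r.hy5_background >= thr5)
            and (r.hy3_signal - r.hy3_background >= thr3)
            for r in scan.itertuples()
        ]
        assert list(filter_spots(scan)) == oracle

    def test_spot_ratio_and_swap_symmetry(self):
        scan = make_scan(
            [{"probe_id": "a", "hy5_signal": 70, "hy3_signal": 35},
             {"probe_id": "b", "hy5_signal": 35, "hy3_signal": 70}]
        )
        r = spot_ratio(scan)
        assert list(r) == [2.0, 0.5]
        swapped = scan.rename(columns={
            "hy5_signal": "hy3_signal", "hy3_signal": "hy5_signal",
            "hy5_background": "hy3_background", "hy3_background": "hy5_background"})
        assert list(spot_ratio(swapped)) == [0.5, 2.0]


class TestNormalization:
    def test_calibrator_normalize_divides_by_median(self):
        ratios = pd.Series([2.0, 2.0, 3.0])
        is_cal = pd.Series([True, True, False])
        out = calibrator_normalize(ratios, is_cal)
        assert out.iloc[2] == 1.5
        assert np.median(out[is_cal]) == 1.0

    def test_no_calibrators_is_an_error(self):
        with pytest.raises(ValueError, match="calibrator"):
            calibrator_normalize(pd.Series([1.0]), pd.Series([False]))

    def test_global_channel_scaling_is_absorbed(self, small_design):
        """Multiplying all Hy5 intensities by c leaves normalized ratios
        unchanged (calibrators absorb per-channel gain)."""
        truth = PlantedTruth(folds={"p01": 3.0}, noise_cv=0.05, seed=2)
        (scan,) = gen_array_scans(small_design, truth, n_arrays=1)
        scaled = scan.copy()
        scaled["hy5_signal"] *= 7.0
        scaled["hy5_background"] *= 7.0
        base = enrich_pipeline([scan])["mean_ratio"]
        scal = enrich_pipeline([scaled])["mean_ratio"]
        pd.testing.assert_series_equal(base, scal, rtol=1e-9)

    def test_probe_mean_ratio(self):
        ratios = pd.Series([2.0, 2.0, 2.0, 2.0, 1.0, 3.0])
        probes = pd.Series(["a"] * 4 + ["b"] * 2)
        means = probe_mean_ratio(ratios, probes)
        assert means["a"] == 2.0 and means["b"] == 2.0


class TestClassification:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ([1.6, 1.8, 2.0], "mito"),
            ([0.5, 0.6, 0.55], "cyto"),
            ([1.6, 1.2, 1.8], "unchanged"),
            ([1.0, 1.0, 1.0], "unchanged"),
        ],
    )
    def test_per_array_rule(self, ratios, expected):
        mat = pd.DataFrame([ratios], index=["p"],
                           columns=["array_1", "array_2", "array_3"])
        res = classify_enrichment(mat, cutoff=1.5)
        assert res.loc["p", "enrichment_class"] == expected

    def test_fold_reported_in_call_direction(self):
        mat = pd.DataFrame([[0.5, 0.5, 0.5]], index=["p"],
                           columns=["array_1", "array_2", "array_3"])
        res = classify_enrichment(mat)
        assert res.loc["p", "fold"] == pytest.approx(2.0)

    def test_cutoff_must_exceed_one(self):
        mat = pd.DataFrame([[2.0]], index=["p"], columns=["array_1"])
        with pytest.raises(ValueError):
            classify_enrichment(mat, cutoff=1.0)

    def test_min_arrays_controls_filtering(self):
        mat = pd.DataFrame([[2.0, np.nan, 2.0]], index=["p"],
                           columns=["array_1", "array_2", "array_3"])
        assert classify_enrichment(mat).loc["p", "enrichment_class"] == "filtered"
        assert (
            classify_enrichment(mat, min_arrays=2).loc["p", "enrichment_class"]
            == "mito"
        )

    @staticmethod
    def _swap(scans):
        return [
            s.rename(columns={
                "hy5_signal": "hy3_signal", "hy3_signal": "hy5_signal",
                "hy5_background": "hy3_background", "hy3_background": "hy5_background",
            })
            for s in scans
        ]

    def test_channel_swap_antisymmetry_exact_on_replicate_consistent_spots(
        self, small_design
    ):
        """With identical replicate spots the probe mean equals each spot
        ratio, so swapping Hy5 and Hy3 negates log2 ratios exactly and swaps
        the mito/cyto calls."""
        truth = PlantedTruth(folds={"p01": 3.0, "p02": 0.3}, noise_cv=0.0, seed=6)
        scans = gen_array_scans(small_design, truth, n_arrays=3)
        a = enrich_pipeline(scans)
        b = enrich_pipeline(self._swap(scans))
        mapping = {"mito": "cyto", "cyto": "mito", "unchanged": "unchanged",
                   "filtered": "filtered"}
        assert list(b["enrichment_class"]) == [
            mapping[c] for c in a["enrichment_class"]
        ]
        np.testing.assert_allclose(b["log2_ratio"], -a["log2_ratio"], atol=1e-9)

    def test_channel_swap_swaps_calls_under_noise(self, small_design):
        """With replicate noise the arithmetic mean of spot ratios is not
        exactly reciprocal under the swap, but well-separated calls still
        swap mito <-> cyto."""
        truth = PlantedTruth(folds={"p01": 3.0, "p02": 0.3}, noise_cv=0.05, seed=6)
        scans = gen_array_scans(small_design, truth, n_arrays=3)
        a = enrich_pipeline(scans)
        b = enrich_pipeline(self._swap(scans))
        assert a.loc["p01", "enrichment_class"] == "mito"
        assert b.loc["p01", "enrichment_class"] == "cyto"
        assert a.loc["p02", "enrichment_class"] == "cyto"
        assert b.loc["p02", "enrichment_class"] == "mito"
        np.testing.assert_allclose(b["log2_ratio"], -a["log2_ratio"], atol=0.05)


class TestPipelineOracle:
    def test_full_chain_equals_straight_line_recomputation(self, small_design):
        """The pipeline equals an independent step-by-step recomputation."""
        truth = PlantedTruth(folds={"p01": 4.0, "p02": 0.25}, noise_cv=0.2, seed=21)
        scans = gen_array_scans(small_design, truth, n_arrays=3)
        res = enrich_pipeline(scans, cutoff=1.5)

        oracle_cols = {}
        for ai, scan in enumerate(scans, start=1):
            thr5 = float(np.median(scan["hy5_background"]))
            thr3 = float(np.median(scan["hy3_background"]))
            per_probe: dict[str, list[float]] = {}
            cal_ratios = []
            rows = []
            for r in scan.itertuples():
                n5 = r.hy5_signal - r.hy5_background
                n3 = r.hy3_signal - r.hy3_background
                if n5 >= thr5 and n3 >= thr3 and n3 > 0:
                    rows.append((r.probe_id, n5 / n3, r.is_calibrator))
            for pid, ratio, is_cal in rows:
                if is_cal:
                    cal_ratios.append(ratio)
            cal_med = float(np.median(cal_ratios))
            for pid, ratio, _ in rows:
                per_probe.setdefault(pid, []).append(ratio / cal_med)
            oracle_cols[f"array_{ai}"] = {
                pid: float(np.mean(v)) for pid, v in per_probe.items()
            }
        oracle = pd.DataFrame(oracle_cols)
        got = per_array_ratios(scans)
        pd.testing.assert_frame_equal(
            got.dropna(how="all"), oracle.reindex(got.dropna(how="all").index),
            rtol=1e-12,
        )
        # classification agrees with a literal reading of the rule
        for pid, row in oracle.iterrows():
            vals = row.dropna()
            if len(vals) < 3:
                expected = "filtered"
            elif (vals >= 1.5).all():
                expected = "mito"
            elif (vals <= 1 / 1.5).all():
                expected = "cyto"
            else:
                expected = "unchanged"
            assert res.loc[pid, "enrichment_class"] == expected


class TestHeatmapTable:
    def test_log2_values_and_row_count(self, small_design):
        truth = PlantedTruth(folds={"p01": 4.0, "p02": 0.25}, noise_cv=0.0, seed=5)
        scans = gen_array_scans(small_design, truth, n_arrays=2)
        res = enrich_pipeline(scans)
        table = heatmap_table(res)
        n_diff = (res["enrichment_class"].isin(["mito", "cyto"])).sum()
        assert len(table) == n_diff == 2
        assert table.loc["p01", "array_1"] == pytest.approx(2.0)  # log2(4)
        assert res.loc["p02", "log2_ratio"] == pytest.approx(-2.0)
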