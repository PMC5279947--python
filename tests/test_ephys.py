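"""Unit and property tests for the fiber-volley-normalized analysis pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synredist import (
    EventTrain,
    average_by_intensity,
    bin_by_fiber_volley,
    complete_bins,
    event_summary,
    exclude_saturated,
    flag_saturation,
    paired_pulse_ratio,
    percent_change,
    response_fv_ratio,
    unweighted_means_test,
)


def _sweeps(rows):
    """Sweep table from (slice, group, cell, stim, fv, fepsp, epsc, sat) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "slice_id", "group", "cell_id", "stimulus_v",
            "fv_uv", "fepsp_slope", "epsc_pa", "saturated",
        ],
    )


class TestAverageByIntensity:
    def test_idempotent_on_constant_sweeps(self):
        rows = [("s1", "g", "c1", 10.0, 100.0, 0.5, 240.0, False)] * 10
        out = average_by_intensity(_sweeps(rows))
        assert len(out) == 1
        assert out.loc[0, "epsc_pa"] == 240.0
        assert out.loc[0, "fv_uv"] == 100.0
        assert not out.loc[0, "saturated"]

    def test_arithmetic_mean_and_majority_vote(self):
        rows = [
            ("s1", "g", "c1", 10.0, 90.0, 0.4, 100.0, True),
            ("s1", "g", "c1", 10.0, 110.0, 0.6, 120.0, True),
            ("s1", "g", "c1", 10.0, 100.0, 0.5, 110.0, False),
        ]
        out = average_by_intensity(_sweeps(rows))
        assert out.loc[0, "epsc_pa"] == pytest.approx(110.0)
        assert out.loc[0, "fv_uv"] == pytest.approx(100.0)
        assert bool(out.loc[0, "saturated"])

    def test_noise_shrinks_with_averaging(self):
        # averaged EPSC should fall within 3 sigma/sqrt(10) of the noiseless value
        rng = np.random.default_rng(0)
        sigma, true = 30.0, 300.0
        rows = [
            ("s1", "g", "c1", 10.0, 100.0, 0.5, true + sigma * rng.standard_normal(), False)
            for _ in range(10)
        ]
        out = average_by_intensity(_sweeps(rows))
        assert abs(out.loc[0, "epsc_pa"] - true) < 3 * sigma / np.sqrt(10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_by_intensity(_sweeps([]))


class TestSaturationHandling:
    def test_no_saturated_rows_is_identity(self):
        table = _sweeps([("s1", "g", "c1", 10.0, 100.0, 0.5, 240.0, False)] * 3)
        pd.testing.assert_frame_equal(exclude_saturated(table), table)

    def test_all_saturated_yields_empty_with_warning(self):
        table = _sweeps([("s1", "g", "c1", 10.0, 400.0, 0.5, 240.0, True)] * 3)
        with pytest.warns(UserWarning, match="saturated"):
            out = exclude_saturated(table)
        assert out.empty

    def test_mixed_rows_counted(self):
        rows = [("s1", "g", "c1", float(i), 100.0, 0.5, 240.0, i % 2 == 0) for i in range(6)]
        out = exclude_saturated(_sweeps(rows))
        assert len(out) == 3

    def test_plateau_detector_flags_top_of_io_curve(self):
        # FV growth stalls at the last two intensities -> both flagged? only the
        # second plateau point is flagged (the rule needs a preceding near-max response)
        rows = [
            ("s1", "g", "c1", 10.0, 100.0, 0.5, 100.0, False),
            ("s1", "g", "c1", 20.0, 200.0, 0.5, 200.0, False),
            ("s1", "g", "c1", 40.0, 398.0, 0.5, 390.0, False),
            ("s1", "g", "c1", 80.0, 400.0, 0.5, 395.0, False),
        ]
        out = flag_saturation(_sweeps(rows))
        assert list(out["saturated"]) == [False, False, False, True]


class TestBinning:
    def test_half_open_bins_and_counts(self):
        rows = [
            ("s1", "g", "c1", 1.0, 50.0, 0.1, 10.0, False),
            ("s1", "g", "c1", 2.0, 120.0, 0.2, 20.0, False),
            ("s1", "g", "c1", 3.0, 180.0, 0.3, 30.0, False),
        ]
        out = bin_by_fiber_volley(_sweeps(rows), 100.0, "epsc")
        assert list(out["n"]) == [1, 2]
        assert list(out["bin_low"]) == [0.0, 100.0]
        assert out.loc[1, "mean_response"] == pytest.approx(25.0)
        assert np.isnan(out.loc[0, "sem"])  # singleton bin: SEM undefined

    def test_noiseless_linear_data_bin_means(self):
        # with EPSC = r * FV exactly, each bin mean is r * mean FV of its members
        r = 2.44
        fvs = np.array([10.0, 60.0, 140.0, 160.0, 230.0, 260.0, 290.0])
        rows = [("s1", "g", "c1", float(i), fv, 0.1, r * fv, False) for i, fv in enumerate(fvs)]
        out = bin_by_fiber_volley(_sweeps(rows), 100.0, "epsc")
        for _, row in out.iterrows():
            members = fvs[(fvs >= row["bin_low"]) & (fvs < row["bin_high"])]
            assert row["mean_response"] == pytest.approx(r * members.mean())

    def test_bin_width_conventions(self, control_responses):
        # both published widths partition all retained responses
        for width in (75.0, 100.0):
            out = bin_by_fiber_volley(control_responses, width, "epsc")
            assert out["n"].sum() == len(control_responses)

    def test_invalid_inputs(self, control_responses):
        with pytest.raises(ValueError, match="bin_width"):
            bin_by_fiber_volley(control_responses, 0.0)
        with pytest.raises(ValueError, match="measure"):
            bin_by_fiber_volley(control_responses, 100.0, "latency")

    @settings(derandomize=True, max_examples=30)
    @given(
        fvs=st.lists(st.floats(0.0, 399.0), min_size=1, max_size=40),
        width=st.sampled_from([50.0, 75.0, 100.0]),
    )
    def test_binning_partitions_responses(self, fvs, width):
        rows = [("s1", "g", "c1", float(i), fv, 0.1, fv, False) for i, fv in enumerate(fvs)]
        out = bin_by_fiber_volley(_sweeps(rows), width, "epsc")
        assert out["n"].sum() == len(fvs)
        assert (out["bin_high"] - out["bin_low"]).eq(width).all()


class TestResponseFvRatio:
    def test_single_response_ratio(self):
        per, summary = response_fv_ratio(
            _sweeps([("s1", "g", "c1", 10.0, 100.0, 0.5, 240.0, False)])
        )
        assert per["ratio"].iloc[0] == pytest.approx(2.4)
        assert summary.loc[0, "mean_ratio"] == pytest.approx(2.4)

    def test_constant_ratios_have_zero_sem(self):
        rows = [("s1", "g", "c1", float(i), 100.0 * i, 0.5, 150.0 * i, False) for i in (1, 2, 3)]
        _, summary = response_fv_ratio(_sweeps(rows))
        assert summary.loc[0, "mean_ratio"] == pytest.approx(1.5)
        assert summary.loc[0, "sem"] == pytest.approx(0.0)

    def test_zero_fv_rows_excluded_with_warning(self):
        rows = [
            ("s1", "g", "c1", 1.0, 0.0, 0.5, 100.0, False),
            ("s1", "g", "c1", 2.0, 100.0, 0.5, 240.0, False),
        ]
        with pytest.warns(UserWarning, match="zero fiber volley"):
            per, summary = response_fv_ratio(_sweeps(rows))
        assert len(per) == 1 and summary.loc[0, "n"] == 1

    def test_scale_equivariance(self, control_responses):
        c = 3.0
        scaled = control_responses.assign(epsc_pa=control_responses["epsc_pa"] * c)
        _, base = response_fv_ratio(control_responses)
        _, after = response_fv_ratio(scaled)
        assert after["mean_ratio"].iloc[0] == pytest.approx(c * base["mean_ratio"].iloc[0])
        binned_base = bin_by_fiber_volley(control_responses, 100.0, "epsc")
        binned_after = bin_by_fiber_volley(scaled, 100.0, "epsc")
        np.testing.assert_allclose(
            binned_after["mean_response"], c * binned_base["mean_response"]
        )

    def test_saturation_invariance(self, control_responses):
        # appending saturated rows changes nothing downstream
        extra = control_responses.head(5).assign(saturated=True, fv_uv=390.0)
        augmented = pd.concat([control_responses, extra], ignore_index=True)
        kept = exclude_saturated(augmented)
        _, base = response_fv_ratio(control_responses)
        _, after = response_fv_ratio(kept)
        pd.testing.assert_frame_equal(base, after)


class TestPairedPulseRatio:
    @pytest.mark.parametrize("a1, a2, expected", [(100.0, 90.0, 0.9), (57.0, 57.0, 1.0)])
    def test_ratio(self, a1, a2, expected):
        assert paired_pulse_ratio(a1, a2) == pytest.approx(expected)

    def test_nonpositive_first_pulse_rejected(self):
        with pytest.raises(ValueError):
            paired_pulse_ratio(0.0, 50.0)

    def test_recovers_generator_depression_factor(self):
        from synredist import make_paired_pulses, preset_config

        trials = make_paired_pulses(preset_config("control", seed=7), n_trials=50)
        ratios = paired_pulse_ratio(trials["amp1_pa"], trials["amp2_pa"])
        sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.9) < 2 * sem


class TestEventSummary:
    def test_frequency_and_amplitude(self):
        train = EventTrain("c1", 60.0, np.linspace(0, 59, 30), np.full(30, 20.0))
        freq, amp = event_summary(train)
        assert freq == pytest.approx(0.5)
        assert amp == pytest.approx(20.0)

    def test_empty_train(self):
        freq, amp = event_summary(EventTrain("c1", 60.0, np.array([]), np.array([])))
        assert freq == 0.0
        assert np.isnan(amp)

    def test_invalid_trains_rejected(self):
        with pytest.raises(ValueError):
            EventTrain("c1", 0.0, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            EventTrain("c1", 10.0, np.array([11.0]), np.array([5.0]))


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, test, expected",
        [
            (16_881, 23_756, 41),   # enhanced neurogenesis, stem-cell Bax deletion
            (17_910, 26_508, 48),   # enhanced neurogenesis, postmitotic Bax deletion
            (7_648, 5_601, -27),    # ablated neurogenesis (Dcx+ cells)
            (123.0, 123.0, 0),
        ],
    )
    def test_reported_changes(self, ref, test, expected):
        assert percent_change(ref, test) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)


def _binned_from_cells(cells):
    """Binned-summary frame from {(group, bin_low): values} raw data."""
    rows = []
    for (group, bin_low), values in cells.items():
        v = np.asarray(values, dtype=float)
        rows.append(
            {
                "group": group,
                "bin_low": bin_low,
                "bin_high": bin_low + 100.0,
                "mean_response": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(v.size),
                "n": v.size,
            }
        )
    return pd.DataFrame(rows)


def _harmonic_oracle(cells):
    """Independent unweighted-means ANOVA via explicit loops."""
    groups = sorted({g for g, _ in cells})
    bins = sorted({b for _, b in cells})
    a, b = len(groups), len(bins)
    means = {k: float(np.mean(v)) for k, v in cells.items()}
    inv_n = sum(1.0 / len(cells[(g, j)]) for g in groups for j in bins)
    n_h = a * b / inv_n
    grand = np.mean([means[(g, j)] for g in groups for j in bins])
    row = {g: np.mean([means[(g, j)] for j in bins]) for g in groups}
    col = {j: np.mean([means[(g, j)] for g in groups]) for j in bins}
    ss_g = n_h * b * sum((row[g] - grand) ** 2 for g in groups)
    ss_b = n_h * a * sum((col[j] - grand) ** 2 for j in bins)
    ss_e, df_e = 0.0, 0
    for v in cells.values():
        v = np.asarray(v, dtype=float)
        ss_e += float(np.sum((v - v.mean()) ** 2))
        df_e += v.size - 1
    ms_e = ss_e / df_e
    return ss_g / (a - 1) / ms_e, ss_b / (b - 1) / ms_e


class TestUnweightedMeansTest:
    def test_unbalanced_2x3_matches_hand_oracle(self):
        cells = {
            ("ctrl", 0.0): [10.1, 11.2],
            ("ctrl", 100.0): [19.8, 21.4, 20.9],
            ("ctrl", 200.0): [30.3, 31.7, 29.8, 30.9, 31.1],
            ("ko", 0.0): [8.2, 7.9, 8.8],
            ("ko", 100.0): [15.5, 16.0, 14.8, 15.2],
            ("ko", 200.0): [24.4, 25.6],
        }
        res = unweighted_means_test(_binned_from_cells(cells))
        f_g, f_b = _harmonic_oracle(cells)
        assert res.F_group == pytest.approx(f_g, abs=1e-10)
        assert res.F_bin == pytest.approx(f_b, abs=1e-10)
        assert res.df_error == sum(len(v) - 1 for v in cells.values())

    def test_balanced_design_equals_standard_anova(self):
        # balanced case: unweighted-means F must equal the classical two-way
        # ANOVA F from raw sums of squares (independent brute-force oracle)
        rng = np.random.default_rng(42)
        groups, bins, n = ["a", "b"], [0.0, 100.0, 200.0], 4
        cells = {
            (g, j): rng.normal(10 + 5 * bins.index(j) + 2 * groups.index(g), 1.5, n)
            for g in groups
            for j in bins
        }
        res = unweighted_means_test(_binned_from_cells(cells))

        data = np.stack([cells[(g, j)] for g in groups for j in bins])
        data = data.reshape(len(groups), len(bins), n)
        grand = data.mean()
        ss_group = n * len(bins) * np.sum((data.mean(axis=(1, 2)) - grand) ** 2)
        ss_bin = n * len(groups) * np.sum((data.mean(axis=(0, 2)) - grand) ** 2)
        ss_err = np.sum((data - data.mean(axis=2, keepdims=True)) ** 2)
        df_err = data.size - len(groups) * len(bins)
        f_group = (ss_group / (len(groups) - 1)) / (ss_err / df_err)
        f_bin = (ss_bin / (len(bins) - 1)) / (ss_err / df_err)
        assert res.F_group == pytest.approx(f_group, abs=1e-10)
        assert res.F_bin == pytest.approx(f_bin, abs=1e-10)

    def test_identical_groups_give_zero_f(self):
        shared = {0.0: [10.0, 11.0, 12.0], 100.0: [20.0, 21.0, 22.0]}
        cells = {(g, j): v for g in ("a", "b") for j, v in shared.items()}
        res = unweighted_means_test(_binned_from_cells(cells))
        assert res.F_group == pytest.approx(0.0, abs=1e-12)
        assert res.p_group == pytest.approx(1.0)

    def test_small_cells_rejected(self):
        cells = {
            ("a", 0.0): [1.0],
            ("a", 100.0): [2.0, 3.0],
            ("b", 0.0): [1.5, 2.5],
            ("b", 100.0): [2.0, 2.2],
        }
        with pytest.raises(ValueError, match="n < 2"):
            unweighted_means_test(_binned_from_cells(cells))

    def test_incomplete_crossing_rejected(self):
        cells = {
            ("a", 0.0): [1.0, 2.0],
            ("a", 100.0): [2.0, 3.0],
            ("b", 0.0): [1.5, 2.5],
        }
        with pytest.raises(ValueError, match="incomplete|levels"):
            unweighted_means_test(_binned_from_cells(cells))

    def test_complete_bins_filters_unshared_bins(self):
        cells = {
            ("a", 0.0): [1.0, 2.0],
            ("a", 100.0): [2.0, 3.0],
            ("b", 100.0): [1.5, 2.5],
            ("b", 200.0): [4.0, 5.0],
        }
        out = complete_bins(_binned_from_cells(cells))
        assert set(out["bin_low"]) == {100.0}
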