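import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqdiff import (
    apply_manual_exclusions,
    apply_missingness_filter,
    build_qc_report,
    compute_hemolysis_dcq,
    detect_reference_outlier_samples,
    spike_in_report,
)

from conftest import make_cq

PAIR = ("m23a", "m451a")


def hemo_cq(values):
    return make_cq(values, roles={"m23a": "reference", "m451a": "hemolysis_marker"},
                   assays=["m23a", "m451a"])


class TestHemolysis:
    def test_equal_markers_give_zero_dcq(self):
        out = compute_hemolysis_dcq(hemo_cq([[24.0, 24.0]]), PAIR)
        assert out.loc["s1", "hemolysis_dcq"] == 0.0
        assert out.loc["s1", "hemolysis_flag"] == False  # noqa: E712

    @pytest.mark.parametrize(
        "dcq,flagged", [(7.26, True), (7.76, True), (8.43, True), (8.68, True),
                        (7.00, False), (6.99, False)]
    )
    def test_strict_threshold_at_seven(self, dcq, flagged):
        out = compute_hemolysis_dcq(hemo_cq([[20.0 + dcq, 20.0]]), PAIR)
        assert out.loc["s1", "hemolysis_dcq"] == pytest.approx(dcq)
        assert bool(out.loc["s1", "hemolysis_flag"]) is flagged

    def test_missing_marker_yields_missing_flag_and_warning(self):
        cq = hemo_cq([[24.0, np.nan], [28.0, 20.0]])
        with pytest.warns(UserWarning, match="markers missing"):
            out = compute_hemolysis_dcq(cq, PAIR)
        assert pd.isna(out.loc["s1", "hemolysis_dcq"])
        assert pd.isna(out.loc["s1", "hemolysis_flag"])
        assert bool(out.loc["s2", "hemolysis_flag"])

    def test_absent_marker_assay_is_hard_error(self, tiny_cq):
        with pytest.raises(KeyError, match="hemolysis marker"):
            compute_hemolysis_dcq(tiny_cq, ("a1", "nope"))

    @given(
        cq23=st.floats(15, 40), cq451=st.floats(15, 40),
        up=st.floats(0, 5), down=st.floats(0, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_flag_monotone_in_contamination(self, cq23, cq451, up, down):
        """Raising Cq(miR-23a) or lowering Cq(miR-451a) never un-flags."""
        base = compute_hemolysis_dcq(hemo_cq([[cq23, cq451]]), PAIR)
        more = compute_hemolysis_dcq(
            hemo_cq([[min(cq23 + up, 45.0), max(cq451 - down, 0.1)]]), PAIR
        )
        if bool(base.loc["s1", "hemolysis_flag"]):
            assert bool(more.loc["s1", "hemolysis_flag"])


class TestSpikeIns:
    def test_identical_spike_cq_all_pass(self):
        cq = make_cq([[19.0], [19.0], [19.0]], roles={"UniSp2": "spike_in"}, assays=["UniSp2"])
        per_sample, summary = spike_in_report(cq)
        assert not per_sample["UniSp2_warn"].any()
        assert summary.loc["UniSp2", "n_warned"] == 0
        assert summary.loc["UniSp2", "min_cq"] == summary.loc["UniSp2", "max_cq"] == 19.0

    def test_three_cycle_deviation_warns_with_window_two(self):
        cq = make_cq([[19.0], [19.0], [19.0], [22.0]],
                     roles={"UniSp2": "spike_in"}, assays=["UniSp2"])
        per_sample, summary = spike_in_report(cq, window=2.0)
        assert list(per_sample["UniSp2_warn"]) == [False, False, False, True]
        assert summary.loc["UniSp2", "n_warned"] == 1

    def test_partial_annotation_covers_present_spikes_only(self):
        cq = make_cq([[25.6, 30.0]], roles={"UniSp4": "spike_in", "t": "target"},
                     assays=["UniSp4", "t"])
        per_sample, summary = spike_in_report(cq, spike_ids=["UniSp4", "UniSp2"])
        assert list(summary.index) == ["UniSp4"]

    def test_no_spikes_warns_and_continues(self, tiny_cq):
        with pytest.warns(UserWarning, match="no spike-in"):
            per_sample, summary = spike_in_report(tiny_cq, spike_ids=[])
        assert summary.empty


class TestReferenceOutliers:
    def ref_cq(self, means):
        # one reference assay, so per-sample mean reference Cq == the value
        return make_cq([[m] for m in means], roles={"ref": "reference"}, assays=["ref"])

    def test_flags_low_input_sample(self):
        out = detect_reference_outlier_samples(self.ref_cq([29.0, 29.5, 30.03, 34.67]))
        assert list(out["reference_outlier_flag"]) == [False, False, False, True]
        assert out["mean_reference_cq"].iloc[3] == pytest.approx(34.67)

    def test_gap_rule_flags_same_sample(self):
        out = detect_reference_outlier_samples(
            self.ref_cq([29.0, 29.5, 30.03, 34.67]), rule="gap", gap=3.0
        )
        assert list(out["reference_outlier_flag"]) == [False, False, False, True]

    def test_equal_means_no_flags(self):
        out = detect_reference_outlier_samples(self.ref_cq([30.0] * 5))
        assert not out["reference_outlier_flag"].any()

    def test_single_sample_no_flag_with_warning(self):
        with pytest.warns(UserWarning, match="single sample"):
            out = detect_reference_outlier_samples(self.ref_cq([30.0]))
        assert not out["reference_outlier_flag"].any()

    def test_all_references_missing_flags_no_signal(self):
        cq = make_cq([[np.nan, 20.0], [30.0, 21.0]],
                     roles={"ref": "reference", "t": "target"}, assays=["ref", "t"])
        out = detect_reference_outlier_samples(cq)
        assert bool(out.loc["s1", "reference_outlier_flag"])
        assert out.loc["s1", "outlier_reason"] == "no_reference_signal"

    def test_mean_over_present_references(self):
        cq = make_cq([[30.0, np.nan, 32.0]],
                     roles={f"r{i}": "reference" for i in (1, 2, 3)},
                     assays=["r1", "r2", "r3"])
        out = detect_reference_outlier_samples(cq, ["r1", "r2", "r3"])
        assert out.loc["s1", "mean_reference_cq"] == pytest.approx(31.0)


class TestMissingnessFilter:
    def cq_with_missing(self, n_missing, n_samples=20):
        col = [np.nan] * n_missing + [28.0] * (n_samples - n_missing)
        full = [[v, 30.0] for v in col]
        return make_cq(full, assays=["t1", "ref"], roles={"ref": "reference"})

    @pytest.mark.parametrize("n_missing,excluded", [(11, True), (10, False), (0, False)])
    def test_strictly_more_than_half(self, n_missing, excluded):
        retained, dropped, table = apply_missingness_filter(self.cq_with_missing(n_missing))
        assert ("t1" in dropped) is excluded
        if excluded:
            assert table.loc["t1", "exclusion_reason"] == "missingness"

    def test_reference_assays_exempt_but_reported(self):
        vals = [[np.nan, np.nan]] * 15 + [[28.0, 30.0]] * 5
        cq = make_cq(vals, assays=["t1", "ref"], roles={"ref": "reference"})
        retained, dropped, table = apply_missingness_filter(cq)
        assert dropped == ["t1"]
        assert "ref" in retained
        assert table.loc["ref", "missing_fraction"] == pytest.approx(0.75)


class TestManualExclusions:
    def test_assay_exclusion_shrinks_panel(self, tiny_cq):
        out, log = apply_manual_exclusions(tiny_cq, [("a4", "assay", "nonspecific_amplification")])
        assert len(out.assay_ids) == len(tiny_cq.assay_ids) - 1
        assert log.iloc[0]["reason"] == "nonspecific_amplification"

    def test_empty_list_is_identity(self, tiny_cq):
        out, log = apply_manual_exclusions(tiny_cq, [])
        pd.testing.assert_frame_equal(out.values, tiny_cq.values)
        assert log.empty

    def test_idempotent_double_exclusion(self, tiny_cq):
        out, log = apply_manual_exclusions(
            tiny_cq,
            [("a4", "assay", "nonspecific_amplification"), ("a4", "assay", "again")],
        )
        assert len(log) == 1

    def test_unknown_id_is_error(self, tiny_cq):
        with pytest.raises(KeyError, match="unknown assay"):
            apply_manual_exclusions(tiny_cq, [("nope", "assay", "x")])

    def test_sample_exclusion(self, tiny_cq):
        out, log = apply_manual_exclusions(tiny_cq, [("s2", "sample", "outlier")])
        assert out.sample_ids == ["s1"]


def test_filter_order_insensitive():
    """Missingness filter then manual exclusion retains the same assay set as
    the reverse order."""
    rng = np.random.default_rng(5)
    vals = rng.uniform(20, 36, (20, 6))
    vals[:12, 0] = np.nan  # assay a1: 60% missing
    cq = make_cq(vals)
    manual = [("a3", "assay", "nonspecific_amplification")]

    _, dropped_first, _ = apply_missingness_filter(cq)
    after_m, _ = apply_manual_exclusions(
        cq.subset(assays=[a for a in cq.assay_ids if a not in dropped_first]), manual
    )
    order1 = set(after_m.assay_ids)

    after_manual, _ = apply_manual_exclusions(cq, manual)
    _, dropped_second, _ = apply_missingness_filter(after_manual)
    order2 = {a for a in after_manual.assay_ids if a not in dropped_second}
    assert order1 == order2 == {"a2", "a4", "a5", "a6"}


def test_build_qc_report_assembles_all_gates(default_dataset):
    cq, meta, truth = default_dataset
    report = build_qc_report(cq)
    assert {"hemolysis_dcq", "hemolysis_flag", "mean_reference_cq",
            "reference_outlier_flag"} <= set(report.samples.columns)
    assert {"role", "missing_fraction", "excluded", "exclusion_reason"} <= set(report.assays.columns)
    assert set(report.spike_summary.index) == {"UniSp2", "UniSp4", "UniSp5", "UniSp6"}
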