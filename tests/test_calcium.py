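"""ΔF/F, threshold calibration, activity calls, reaction times, cohorts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinaltone import (
    CalciumCellRecord,
    CalibrationPoint,
    ParameterError,
    Trace,
    calibrate_threshold,
    classify_cell_activity,
    compute_dff,
    detect_calcium_peaks,
    measure_reaction_time,
    summarize_cohort,
)
from spinaltone.synth import (
    CALIBRATION_PROTOCOL,
    gen_calcium_cohort,
    gen_cc_response,
    gen_gcamp_trace,
    get_preset,
)

FS = 2.0  # imaging frame rate, Hz

#: The three printed calibration steps: (pA, mean spikes, mean ΔF/F %).
PRINTED_CALIBRATION = [
    CalibrationPoint(10.0, 0.2, 0.6),
    CalibrationPoint(30.0, 6.6, 3.5),
    CalibrationPoint(80.0, 19.3, 17.5),
]


def _dff_trace(values):
    return Trace(values=np.asarray(values, float), sample_rate=FS, units="percent")


class TestDff:
    def test_constant_trace_all_zero(self):
        tr = Trace(values=np.full(100, 50.0), sample_rate=FS, units="au")
        dff = compute_dff(tr, (0.0, 10.0))
        assert np.allclose(dff.values, 0.0)

    def test_excursion_arithmetic(self):
        v = np.full(100, 100.0)
        v[60] = 103.5
        dff = compute_dff(Trace(values=v, sample_rate=FS, units="au"), (0.0, 10.0))
        assert dff.values.max() == pytest.approx(3.5)

    def test_nonpositive_baseline_rejected(self):
        tr = Trace(values=np.zeros(100), sample_rate=FS, units="au")
        with pytest.raises(ParameterError):
            compute_dff(tr, (0.0, 10.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = 100.0 * (1.0 + 0.05 * rng.standard_normal(200).cumsum() * 0.01 + 0.02)
        a = compute_dff(Trace(values=v, sample_rate=FS, units="au"), (0.0, 20.0))
        b = compute_dff(Trace(values=7.3 * v, sample_rate=FS, units="au"), (0.0, 20.0))
        assert np.allclose(a.values, b.values, atol=1e-9)


class TestPeaks:
    def test_subthreshold_trace_empty(self):
        assert detect_calcium_peaks(_dff_trace(np.full(600, 1.0))).size == 0

    def test_planted_kernel_responses_found(self):
        spikes = [30.0, 90.0, 150.0]
        tr = gen_gcamp_trace(
            [s for s in spikes for _ in range(10)], duration=300.0
        )
        dff = compute_dff(tr, (0.0, 20.0))
        peaks = detect_calcium_peaks(dff)
        assert peaks.size == 3
        for p, s in zip(peaks, spikes):
            assert abs(p - s) <= 1.5  # within one frame of the burst apex

    def test_peak_exactly_at_threshold_excluded(self):
        v = np.zeros(600)
        v[100] = 3.5  # exactly the noise cut-off: "lower than 3.5%" is noise
        v[200] = 3.51
        peaks = detect_calcium_peaks(_dff_trace(v))
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(100.0)

    def test_raising_threshold_never_adds_peaks(self):
        rng = np.random.default_rng(1)
        v = np.abs(rng.normal(2.0, 2.5, 1200))
        tr = _dff_trace(v)
        n = [
            detect_calcium_peaks(tr, threshold_pct=th).size
            for th in (2.0, 3.5, 5.0, 8.0)
        ]
        assert n == sorted(n, reverse=True)


class TestCalibration:
    def test_printed_triple_gives_threshold(self):
        assert calibrate_threshold(PRINTED_CALIBRATION) == pytest.approx(3.5)

    def test_first_point_meeting_criterion_wins(self):
        pts = [
            CalibrationPoint(10.0, 1.2, 0.9),
            CalibrationPoint(30.0, 6.6, 3.5),
        ]
        assert calibrate_threshold(pts) == pytest.approx(0.9)

    def test_no_point_reaching_criterion_rejected(self):
        pts = [CalibrationPoint(10.0, 0.2, 0.6), CalibrationPoint(20.0, 0.8, 1.1)]
        with pytest.raises(ParameterError):
            calibrate_threshold(pts)

    def test_simulated_protocol_monotone_and_threshold_at_first_spiking_step(self):
        cell = get_preset("study_calibration")
        tr, truth = gen_cc_response(cell, CALIBRATION_PROTOCOL, sample_rate=20000.0)
        points = []
        for meta, n_spikes in zip(tr.metadata["steps"], truth.spikes_per_step):
            spikes = [
                s for s in truth.spike_times_s if meta["start_s"] <= s < meta["end_s"]
            ]
            fl = gen_gcamp_trace(spikes, duration=tr.duration + 2.0)
            dff = compute_dff(fl, (0.0, 2.0))
            points.append(
                CalibrationPoint(meta["amplitude_pa"], n_spikes, dff.values.max())
            )
        dffs = [p.mean_dff_pct for p in points]
        spikes = [p.mean_spikes for p in points]
        assert dffs == sorted(dffs)
        assert spikes == sorted(spikes)
        first_spiking = next(p for p in points if p.mean_spikes >= 1)
        assert calibrate_threshold(points) == pytest.approx(first_spiking.mean_dff_pct)


class TestActivityClassification:
    def _record(self, peak_times, duration=900.0):
        v = np.zeros(int(duration * FS))
        for t in peak_times:
            v[int(t * FS)] = 10.0
        return CalciumCellRecord(dff=_dff_trace(v), condition="somatostatin")

    def test_three_peaks_in_five_minutes_is_repeated_bursting(self):
        rec = self._record([100.0, 200.0, 300.0])
        assert classify_cell_activity(rec).label == "repeated_bursting"

    def test_two_peaks_is_active_only(self):
        rec = self._record([100.0, 200.0])
        assert classify_cell_activity(rec).label == "active"

    def test_no_peaks_is_inactive(self):
        rec = self._record([])
        assert classify_cell_activity(rec).label == "inactive"

    def test_three_spread_peaks_not_bursting(self):
        rec = self._record([50.0, 400.0, 800.0])
        assert classify_cell_activity(rec).label == "active"

    def test_bursting_implies_active_label_monotone(self):
        for times in ([], [100.0], [100.0, 150.0, 200.0]):
            rec = classify_cell_activity(self._record(times))
            if rec.label == "repeated_bursting":
                assert len(rec.peaks_s) >= 3


class TestReactionTime:
    def _record(self, peak_times):
        v = np.zeros(int(900 * FS))
        for t in peak_times:
            v[int(t * FS)] = 10.0
        rec = CalciumCellRecord(dff=_dff_trace(v), condition="somatostatin")
        return classify_cell_activity(rec)

    def test_subtraction_anchored_to_drug_arrival(self):
        rec = self._record([6.8 * 60.0])
        assert measure_reaction_time(rec, 60.0) == pytest.approx(5.8)

    def test_no_peaks_absent(self):
        rec = self._record([])
        assert measure_reaction_time(rec, 60.0) is None

    def test_peak_before_arrival_flags_spontaneous(self):
        rec = self._record([30.0, 400.0])
        assert measure_reaction_time(rec, 60.0) is None
        assert rec.spontaneously_active

    def test_control_recording_rejected(self):
        rec = self._record([400.0])
        rec.condition = "control"
        with pytest.raises(ParameterError):
            measure_reaction_time(rec, 60.0)

    def test_planted_latency_distribution_recovered(self):
        traces, truth = gen_calcium_cohort(
            60, responder_fraction=0.5, seed=21, noise_sd=0.3
        )
        rts = []
        for tr in traces:
            dff = compute_dff(tr, (0.0, 60.0))
            rec = CalciumCellRecord(dff=dff, condition="somatostatin")
            classify_cell_activity(rec)
            rt = measure_reaction_time(rec, 60.0)
            if rt is not None:
                rts.append(rt)
        planted = [x for x in truth.extra["latencies_min"] if x is not None]
        sem = np.std(planted, ddof=1) / np.sqrt(len(planted))
        assert np.mean(rts) == pytest.approx(np.mean(planted), abs=max(3 * sem, 0.3))


class TestCohortSummary:
    @pytest.mark.parametrize(
        "n_active,n_total,expected_pct,digits",
        [
            (10, 181, 5.5, 1),
            (96, 274, 35.0, 1),
            (25, 74, 33.8, 1),
            (24, 140, 17.1, 1),
            (10, 17, 59.0, 0),
            (8, 13, 62.0, 0),
            (0, 20, 0.0, 1),
        ],
    )
    def test_percentages_from_counts(self, n_active, n_total, expected_pct, digits):
        records = []
        for i in range(n_total):
            v = np.zeros(600)
            if i < n_active:
                v[300] = 10.0
            rec = CalciumCellRecord(dff=_dff_trace(v), condition="somatostatin")
            records.append(classify_cell_activity(rec))
        s = summarize_cohort(records)
        assert s.n_active == n_active
        assert round(s.percent_active, digits) == pytest.approx(expected_pct)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            summarize_cohort([])

    def test_condition_filter(self):
        recs = []
        for cond in ("control", "somatostatin"):
            v = np.zeros(600)
            v[100] = 10.0
            rec = CalciumCellRecord(dff=_dff_trace(v), condition=cond)
            recs.append(classify_cell_activity(rec))
        s = summarize_cohort(recs, condition="control")
        assert s.n_total == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50.0))
def test_dff_invariant_under_gain_change(scale):
    """Camera gain cancels out of ΔF/F."""
    rng = np.random.default_rng(3)
    v = 100.0 + rng.uniform(-5.0, 20.0, 400)
    a = compute_dff(Trace(values=v, sample_rate=FS, units="au"), (0.0, 30.0))
    b = compute_dff(Trace(values=scale * v, sample_rate=FS, units="au"), (0.0, 30.0))
    assert np.allclose(a.values, b.values, atol=1e-8)
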