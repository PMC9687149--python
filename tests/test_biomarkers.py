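"""Biomarker extraction: APD90 geometry, AM/ANM arithmetic, AOCL scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alternanspop.biomarkers import (
    ANM_THRESHOLD,
    ApdMeasurementError,
    alternans_magnitude,
    anm,
    apd90,
    classify_alternans,
    cycle_length_result,
    restitution_curve,
    summarize_scenario,
)
from alternanspop.pacing import BeatRecord, PacingSchedule, ProtocolRun
from alternanspop.synthetic import APTrainSpec, synth_ap_train


def _single_beat(apd=200.0, cl=600.0, **kw):
    spec = APTrainSpec(apd90s=(apd,), cycle_length=cl, **kw)
    t, v, _ = synth_ap_train(spec)
    return t, v


class TestApd90:
    @pytest.mark.parametrize("planted", [60.0, 120.0, 200.0, 350.0])
    def test_recovers_planted_apd(self, planted):
        t, v = _single_beat(apd=planted, cl=500.0)
        assert apd90(t, v) == pytest.approx(planted, abs=0.5)

    def test_square_pulse_apd_is_pulse_width(self):
        # idealized square AP: threshold crossing at the falling edge
        dt, w = 0.1, 150.0
        t = np.arange(0, 4000) * dt
        v = np.where((t >= 1.0) & (t < 1.0 + w), 30.0, -85.0)
        assert apd90(t, v) == pytest.approx(w, abs=2 * dt)

    def test_voltage_offset_invariance(self):
        t, v = _single_beat()
        assert apd90(t, v + 17.3) == pytest.approx(apd90(t, v), abs=1e-9)

    def test_no_capture_raises(self):
        t = np.arange(0, 3000) * 0.1
        v = np.full_like(t, -85.0)
        v[10:20] = -62.0  # subthreshold response, amplitude < 30 mV
        with pytest.raises(ApdMeasurementError):
            apd90(t, v)

    def test_incomplete_repolarization_raises(self):
        t = np.arange(0, 2000) * 0.1
        v = np.where(t < 1.0, -85.0, 30.0)  # never comes back down
        with pytest.raises(ApdMeasurementError):
            apd90(t, v)

    def test_sampling_rate_insensitive(self):
        # interpolated crossing: halving the sampling interval moves
        # APD90 by far less than the interval itself
        spec_a = APTrainSpec(apd90s=(180.0,), cycle_length=500.0, sample_dt=0.1)
        spec_b = APTrainSpec(apd90s=(180.0,), cycle_length=500.0, sample_dt=0.05)
        ta, va, _ = synth_ap_train(spec_a)
        tb, vb, _ = synth_ap_train(spec_b)
        assert abs(apd90(ta, va) - apd90(tb, vb)) < 0.2


class TestAlternansArithmetic:
    def test_constant_sequence_has_zero_magnitude(self):
        assert alternans_magnitude([200.0] * 11) == 0.0
        assert anm([200.0] * 11) == 0.0

    def test_perfect_alternation_magnitude_is_difference(self):
        seq = [250.0 if i % 2 else 210.0 for i in range(11)]
        assert alternans_magnitude(seq) == pytest.approx(40.0)

    def test_printed_alternating_pair(self):
        # 66.3 / 48.8 ms alternation: AM = 17.5, meanAPD ~ 57.55
        seq = [66.3 if i % 2 == 0 else 48.8 for i in range(11)]
        assert alternans_magnitude(seq) == pytest.approx(17.5)
        assert anm(seq) == pytest.approx(17.5 / np.mean(seq[1:]))
        # against the independently stated meanAPD of 56.7 ms
        assert 17.5 / 56.7 == pytest.approx(0.3086, abs=5e-4)

    def test_window_length_enforced(self):
        with pytest.raises(ValueError):
            alternans_magnitude([200.0] * 10)
        with pytest.raises(ValueError):
            alternans_magnitude([200.0] * 12)

    @given(
        st.lists(
            st.floats(min_value=30.0, max_value=500.0),
            min_size=11,
            max_size=11,
        ),
        st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_anm_nonnegative_and_scale_invariant(self, apds, c):
        value = anm(apds)
        assert value >= 0.0
        scaled = [c * a for a in apds]
        assert anm(scaled) == pytest.approx(value, rel=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0455, False), (0.0553, True), (0.05, False), (0.0, False)],
    )
    def test_threshold_is_strict(self, value, expected):
        assert classify_alternans(value) is expected

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            classify_alternans(float("nan"))
        with pytest.raises(ValueError):
            classify_alternans(-0.01)


def _run_from_apds(apds_by_cl: dict, beats_per_cl: int = 12) -> ProtocolRun:
    """Assemble a ProtocolRun from planted per-CL trailing APD values."""
    from alternanspop.ionic import CellState

    schedule = PacingSchedule(
        tuple(sorted(apds_by_cl, reverse=True)), beats_per_cl=beats_per_cl
    )
    beats = {}
    t0 = 0.0
    for cl in schedule.cycle_lengths:
        apds = apds_by_cl[cl]
        pad = [apds[0]] * (beats_per_cl - len(apds))
        full = pad + list(apds)
        records = []
        for i, a in enumerate(full):
            captured = np.isfinite(a)
            records.append(
                BeatRecord(
                    beat_index=i,
                    stim_time=t0 + i * cl,
                    t_upstroke=t0 + i * cl + 1.0,
                    v_peak=40.0 if captured else -30.0,
                    v_rest=-85.0,
                    apd90=a if captured else np.nan,
                    captured=captured,
                )
            )
        beats[cl] = records
        t0 += beats_per_cl * cl
    return ProtocolRun(
        scenario=None,
        schedule=schedule,
        beats=beats,
        final_state=CellState.reference_initial(),
        prepace_beats=0,
    )


def _alternating(mean, delta, n=11):
    return [mean + (delta / 2 if i % 2 else -delta / 2) for i in range(n)]


class TestScenarioSummary:
    def test_no_alternans_yields_zero_pair(self):
        run = _run_from_apds({600.0: [220.0] * 11, 550.0: [210.0] * 11})
        s = summarize_scenario(run)
        assert s.aocl == 0.0 and s.ao_mean_apd == 0.0
        assert s.quality == "ok"
        assert not s.alternans

    def test_aocl_is_longest_qualifying_cl(self):
        run = _run_from_apds(
            {
                650.0: [220.0] * 11,
                600.0: _alternating(200.0, 30.0),
                550.0: _alternating(180.0, 40.0),
            }
        )
        s = summarize_scenario(run)
        assert s.aocl == 600.0
        assert s.ao_mean_apd == pytest.approx(np.mean(_alternating(200.0, 30.0)[1:]))

    def test_single_qualifying_cl(self):
        run = _run_from_apds(
            {600.0: [200.0] * 11, 550.0: _alternating(150.0, 40.0)}
        )
        assert summarize_scenario(run).aocl == 550.0

    def test_incomplete_capture_excluded_and_flagged(self):
        bad = [np.nan if i == 5 else 200.0 for i in range(11)]
        run = _run_from_apds(
            {600.0: bad, 550.0: _alternating(180.0, 40.0)}
        )
        s = summarize_scenario(run)
        assert s.aocl == 550.0
        assert s.quality == "incomplete_capture"

    def test_all_incomplete_is_flagged_not_zeroed(self):
        bad = [np.nan] * 11
        run = _run_from_apds({600.0: bad, 550.0: bad})
        s = summarize_scenario(run)
        assert s.quality == "all_incomplete"

    def test_aocl_in_schedule_or_zero(self):
        run = _run_from_apds(
            {
                700.0: [250.0] * 11,
                600.0: _alternating(200.0, 25.0),
                500.0: _alternating(150.0, 30.0),
            }
        )
        s = summarize_scenario(run)
        assert s.aocl in set(run.schedule.cycle_lengths) | {0.0}


class TestRestitutionCurve:
    def test_linear_mean_apd_gives_planted_slope(self):
        cls_ = [700.0, 600.0, 500.0, 400.0]
        run = _run_from_apds({cl: [0.4 * cl + 30.0] * 11 for cl in cls_})
        df = restitution_curve(run)
        assert len(df) == len(cls_)
        assert np.allclose(df["slope"].to_numpy(), 0.4)

    def test_point_per_complete_cl(self):
        bad = [np.nan] * 11
        run = _run_from_apds({600.0: [230.0] * 11, 500.0: bad})
        assert len(restitution_curve(run)) == 1


class TestPipelineRecovery:
    """Planted alternating AP trains through the full trace pipeline."""

    @pytest.mark.parametrize("delta", [0.0, 10.0, 30.0])
    def test_am_and_anm_recovered_from_traces(self, delta):
        mean_apd = 200.0
        apds = tuple(_alternating(mean_apd, delta, n=11))
        spec = APTrainSpec(apd90s=apds, cycle_length=600.0)
        t, v, records = synth_ap_train(spec)
        measured = []
        for r in records:
            sel = (t >= r.stim_time) & (t < r.stim_time + spec.cycle_length)
            measured.append(apd90(t[sel], v[sel], stim_time=r.stim_time))
        am_true = alternans_magnitude(apds)
        anm_true = anm(apds)
        assert alternans_magnitude(measured) == pytest.approx(am_true, abs=0.5)
        assert anm(measured) == pytest.approx(anm_true, abs=0.01)
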