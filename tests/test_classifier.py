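from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import reference_classify
from seizmon import (
    ClassifierConfig,
    Envelope,
    EventLog,
    StimProgram,
    Transition,
    append_with_capacity,
    classify_stream,
    count_triggers,
    quantize_time,
)


def step_envelope(levels: list[tuple[float, float]], fs: float = 125.0) -> Envelope:
    """Piecewise-constant envelope from (duration_s, value) segments."""
    parts = [np.full(int(d * fs), v) for d, v in levels]
    return Envelope(np.concatenate(parts), fs)


class TestStimProgram:
    def test_defaults_match_device_programs(self):
        from seizmon import default_programs

        p0, p1 = default_programs()
        assert (p0.amplitude_ma, p0.frequency_hz, p0.pulse_width_us, p0.recharge) == \
            (1.0, 125.0, 90.0, "active")
        assert p1.amplitude_ma == 3.0

    def test_invalid_program_rejected(self):
        with pytest.raises(ValueError):
            StimProgram("P0", amplitude_ma=-1.0)
        with pytest.raises(ValueError):
            StimProgram("P2", amplitude_ma=1.0)

    def test_diary_mode_identical_programs_allowed(self):
        p0 = StimProgram("P0", amplitude_ma=1.0)
        p1 = StimProgram("P1", amplitude_ma=1.0)
        cfg = ClassifierConfig(threshold_uv=10.0, program_nonevent=p0, program_event=p1)
        assert cfg.program_nonevent.amplitude_ma == cfg.program_event.amplitude_ma


class TestClassifyStream:
    def test_quiet_envelope_no_transitions(self):
        env = step_envelope([(10.0, 5.0)])
        labels, log = classify_stream(env, ClassifierConfig(threshold_uv=26.7))
        assert not labels.values.any()
        assert len(log) == 0

    def test_single_event_two_transitions(self):
        env = step_envelope([(10.0, 0.0), (10.0, 100.0), (10.0, 0.0)])
        labels, log = classify_stream(env, ClassifierConfig(threshold_uv=26.7))
        assert count_triggers(log) == 2
        assert [tr.raw_time_s for tr in log] == [10.0, 20.0]
        assert [(tr.from_program, tr.to_program) for tr in log] == [
            ("P0", "P1"), ("P1", "P0")
        ]
        fs = env.sampling_rate
        expected = np.zeros(env.n_samples, dtype=bool)
        expected[int(10 * fs):int(20 * fs)] = True
        np.testing.assert_array_equal(labels.values, expected)

    def test_fast_alternation_rate_limited_by_debounce(self):
        segs = [(0.5, 100.0), (0.5, 0.0)] * 20  # 20 s of 0.5 s flapping
        env = step_envelope(segs)
        _, log = classify_stream(env, ClassifierConfig(threshold_uv=26.7))
        times = [tr.raw_time_s for tr in log]
        gaps = np.diff(times)
        assert np.all(gaps >= 2.0 - 1e-12)
        assert count_triggers(log) <= 10

    def test_event_ongoing_at_stream_end_gives_odd_count(self):
        env = step_envelope([(5.0, 0.0), (5.0, 100.0)])
        _, log = classify_stream(env, ClassifierConfig(threshold_uv=26.7))
        assert count_triggers(log) == 1
        assert log.transitions[-1].to_program == "P1"

    @given(
        seed=st.integers(0, 10_000),
        threshold=st.floats(min_value=0.2, max_value=3.0),
        debounce=st.sampled_from([0.25, 0.5, 1.0, 1.5, 2.0, 3.0]),
        fs=st.sampled_from([100.0, 125.0, 250.0]),
    )
    @settings(max_examples=150)
    def test_streaming_equals_per_sample_reference(self, seed, threshold, debounce, fs):
        """The crossing-jump implementation must agree exactly with a
        literal per-sample state machine on random smooth envelopes."""
        rng = np.random.default_rng(seed)
        n = int(20 * fs)
        raw = np.abs(np.cumsum(rng.standard_normal(n)) / np.sqrt(n)) + 0.01
        env = Envelope(raw, fs)
        cfg = ClassifierConfig(threshold_uv=threshold, debounce_s=debounce)
        labels, log = classify_stream(env, cfg)
        ref_labels, ref_transitions = reference_classify(raw, fs, threshold, debounce)
        np.testing.assert_array_equal(labels.values, ref_labels)
        got = [(int(round(tr.raw_time_s * fs)), tr.to_program == "P1") for tr in log]
        assert got == ref_transitions

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_debounce_and_alternation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        fs = 125.0
        raw = np.abs(rng.standard_normal(int(30 * fs))).cumsum() % 5.0
        debounce = float(rng.choice([0.5, 1.0, 2.0]))
        cfg = ClassifierConfig(threshold_uv=2.0, debounce_s=debounce)
        _, log = classify_stream(Envelope(raw, fs), cfg)
        times = [tr.raw_time_s for tr in log]
        assert all(b - a >= debounce - 1e-12 for a, b in zip(times, times[1:]))
        directions = [tr.to_program for tr in log]
        assert all(a != b for a, b in zip(directions, directions[1:]))

    @given(seed=st.integers(0, 10_000), gain=st.floats(min_value=1.0, max_value=3.0))
    @settings(max_examples=50)
    def test_supra_threshold_exposure_monotone_in_gain(self, seed, gain):
        rng = np.random.default_rng(seed)
        raw = np.abs(rng.standard_normal(2000))
        thr = 1.0
        assert np.count_nonzero(gain * raw >= thr) >= np.count_nonzero(raw >= thr)

    def test_labels_reconstructable_from_transitions(self):
        rng = np.random.default_rng(7)
        fs = 125.0
        raw = np.abs(np.cumsum(rng.standard_normal(int(60 * fs))) / 20.0)
        labels, log = classify_stream(
            Envelope(raw, fs), ClassifierConfig(threshold_uv=1.0)
        )
        rebuilt = np.zeros(raw.size, dtype=bool)
        onsets = [tr for tr in log if tr.to_program == "P1"]
        offsets = [tr for tr in log if tr.to_program == "P0"]
        for k, on in enumerate(onsets):
            i0 = int(round(on.raw_time_s * fs))
            i1 = (
                int(round(offsets[k].raw_time_s * fs))
                if k < len(offsets)
                else raw.size
            )
            rebuilt[i0:i1] = True
        np.testing.assert_array_equal(labels.values, rebuilt)


class TestQuantizeTime:
    @pytest.mark.parametrize(
        "t,res,expected", [(3.7, 1.0, 3.0), (3.7, 2.0, 2.0), (4.0, 2.0, 4.0)]
    )
    def test_floor_quantization(self, t, res, expected):
        assert quantize_time(t, res) == expected

    def test_resolution_outside_device_range_rejected(self):
        with pytest.raises(ValueError):
            quantize_time(1.0, 0.5)

    def test_logged_times_are_quantized(self):
        env = step_envelope([(3.7, 0.0), (10.0, 100.0)], fs=10.0)
        _, log = classify_stream(
            Envelope(env.values, 10.0),
            ClassifierConfig(threshold_uv=50.0, log_resolution_s=2.0),
        )
        assert log.transitions[0].raw_time_s == pytest.approx(3.7)
        assert log.transitions[0].time_s == 2.0


class TestEventLog:
    def _tr(self, t, entering=True):
        return Transition(
            time_s=float(int(t)), from_program="P0" if entering else "P1",
            to_program="P1" if entering else "P0", raw_time_s=t,
        )

    def test_rolling_capacity_evicts_oldest(self):
        log = EventLog(capacity=3)
        for k in range(4):
            append_with_capacity(log, self._tr(float(k * 2), entering=k % 2 == 0))
        assert len(log) == 3
        assert count_triggers(log) == 4
        assert log.transitions[0].raw_time_s == 2.0

    def test_single_append(self):
        log = EventLog(capacity=1200)
        append_with_capacity(log, self._tr(1.0))
        assert len(log) == 1

    def test_default_capacity_is_device_memory(self):
        assert ClassifierConfig(threshold_uv=1.0).log_capacity == 1200

    def test_out_of_order_append_rejected(self):
        log = EventLog(capacity=10)
        log.append(self._tr(5.0))
        with pytest.raises(ValueError, match="out-of-order"):
            log.append(self._tr(1.0, entering=False))

    def test_csv_and_json_export(self, tmp_path):
        log = EventLog(capacity=10)
        log.append(self._tr(2.0))
        log.append(self._tr(6.0, entering=False))
        c = tmp_path / "log.csv"
        j = tmp_path / "log.json"
        log.to_csv(c)
        log.to_json(j)
        assert c.read_text().splitlines()[0] == "time_s,from_program,to_program"
        assert "P1" in j.read_text()
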