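import numpy as np
import pytest

import breathloop as bl
from breathloop.errors import ConfigurationError, StreamOrderError
from breathloop.realtime import PEAK, TROUGH, detect_extrema_arrays

from conftest import clean_config, stream_events


class TestIntervalToRate:
    @pytest.mark.parametrize("interval,rate", [(10.0, 6.0), (5.0, 12.0), (15.0, 4.0)])
    def test_reciprocal_of_same_phase_interval(self, interval, rate):
        assert bl.interval_to_rate(interval) == rate

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_interval_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            bl.interval_to_rate(bad)


class TestStreamingDetector:
    def test_flat_input_emits_nothing(self):
        detector = bl.StreamingDetector()
        for k in range(400):
            assert detector.push(k * 0.1, 1.0) == []

    def test_clean_signal_peaks_match_ground_truth(self, clean_signal_factory):
        sig, truth = clean_signal_factory(6.0, 60.0)
        peaks = [e.time for e in stream_events(sig) if e.kind == PEAK]
        assert len(peaks) >= truth.n_breaths - 1
        for t in peaks:
            assert min(abs(t - p) for p in truth.peak_times) <= 0.2

    def test_out_of_order_samples_rejected(self):
        detector = bl.StreamingDetector()
        detector.push(0.0, 0.0)
        detector.push(0.1, 0.5)
        with pytest.raises(StreamOrderError):
            detector.push(0.1, 1.0)
        with pytest.raises(StreamOrderError):
            detector.push(0.05, 1.0)

    def test_refractory_merges_to_more_prominent_peak(self):
        # two bumps 1 s apart with a real dip between them: under a 2 s
        # refractory only the taller one may survive, and the shallow
        # trough between them is dropped with it
        t = np.arange(0, 30, 0.1)
        v = np.interp(t, [0, 2, 2.5, 3, 6, 30], [0, 1.0, 0.3, 0.8, -0.5, -0.5])
        params = bl.DetectorParams(refractory=2.0)
        events = [(e.time, e.kind, e.amplitude)
                  for e in detect_extrema_arrays(t, v, params)]
        assert events == [(0.0, TROUGH, 0.0), (2.0, PEAK, 1.0)]

    def test_refractory_merge_agrees_between_stream_and_offline(self):
        t = np.arange(0, 30, 0.1)
        v = np.interp(t, [0, 2, 2.5, 3, 6, 30], [0, 1.0, 0.3, 0.8, -0.5, -0.5])
        params = bl.DetectorParams(refractory=2.0)
        detector = bl.StreamingDetector(params)
        streamed = []
        for tt, vv in zip(t, v):
            streamed.extend(detector.push(float(tt), float(vv)))
        assert [(e.time, e.kind) for e in streamed] == [(0.0, TROUGH), (2.0, PEAK)]
        offline = detect_extrema_arrays(t, v, params)
        assert [(e.time, e.kind) for e in offline] == [(e.time, e.kind) for e in streamed]

    def test_emitted_kinds_alternate_and_times_increase(self):
        cfg = bl.SimConfig(duration=90.0, seed=2, artifact=bl.ArtifactConfig(burst_amplitude=1.0))
        sig, _ = bl.make_breath_waveform(cfg)
        events = stream_events(sig)
        assert len(events) > 4
        assert all(a.time < b.time for a, b in zip(events, events[1:]))
        assert all(a.kind != b.kind for a, b in zip(events, events[1:]))


class TestOfflineOracle:
    def test_empty_input_gives_empty_list(self):
        assert detect_extrema_arrays(np.array([]), np.array([])) == []

    def test_clean_signal_full_event_inventory(self, clean_signal_factory):
        sig, truth = clean_signal_factory(12.0, 60.0)
        events = bl.detect_extrema_offline(sig)
        peaks = [e for e in events if e.kind == PEAK]
        troughs = [e for e in events if e.kind == TROUGH]
        assert len(peaks) == 12 and len(troughs) == 12
        kinds = [e.kind for e in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        assert np.allclose([e.time for e in peaks], truth.peak_times, atol=0.2)

    @pytest.mark.parametrize("seed", range(8))
    def test_streaming_equivalence_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        amp = [0.0, 0.25, 0.5, 1.0][seed % 4]
        cfg = bl.SimConfig(
            duration=60.0, seed=seed,
            rate_trajectory=bl.RateTrajectory.constant(float(rng.uniform(5, 25))),
            artifact=bl.ArtifactConfig(burst_amplitude=amp) if amp else None,
        )
        sig, _ = bl.make_breath_waveform(cfg)
        window = bl.DetectorParams().rolling_window
        cut = sig.duration - window
        offline = [(e.time, e.kind, e.amplitude)
                   for e in bl.detect_extrema_offline(sig) if e.time < cut]
        streamed = [(e.time, e.kind, e.amplitude)
                    for e in stream_events(sig) if e.time < cut]
        assert streamed == offline


class TestRateEstimator:
    def _feed(self, estimator, times, kind=PEAK):
        out = None
        for t in times:
            out = estimator.update(bl.BreathEvent(t, kind, 1.0))
        return out

    def test_equal_intervals_average_to_rate(self):
        est = bl.RateEstimator(bl.EstimatorParams(window_cycles=3, phase=PEAK))
        result = self._feed(est, [0.0, 10.0, 20.0, 30.0])
        assert result.rate == pytest.approx(6.0)
        assert result.n_cycles == 3

    def test_implausible_interval_rejected_but_anchor_advances(self):
        est = bl.RateEstimator(bl.EstimatorParams(window_cycles=3, phase=PEAK,
                                                  plausible_rate=(2.0, 60.0)))
        result = self._feed(est, [0.0, 10.0, 10.5, 20.5])
        # the 0.5 s interval (120 breaths/min) is discarded; both 10 s ones kept
        assert result.rate == pytest.approx(6.0)
        assert result.n_cycles == 2

    def test_single_event_leaves_rate_undefined(self):
        est = bl.RateEstimator(bl.EstimatorParams(phase=PEAK))
        result = self._feed(est, [0.0])
        assert result.rate is None
        assert result.n_cycles == 0

    def test_opposite_phase_events_ignored(self):
        est = bl.RateEstimator(bl.EstimatorParams(phase=TROUGH))
        assert est.update(bl.BreathEvent(0.0, PEAK, 1.0)) is None

    def test_stale_flag_after_timeout(self):
        params = bl.EstimatorParams(phase=PEAK, staleness_timeout=15.0)
        est = bl.RateEstimator(params)
        self._feed(est, [0.0, 10.0])
        assert not est.estimate_at(20.0).stale
        assert est.estimate_at(25.1).stale

    def test_rate_never_outside_plausible_bounds(self):
        params = bl.EstimatorParams(phase=PEAK, plausible_rate=(4.0, 30.0), window_cycles=4)
        est = bl.RateEstimator(params)
        rng = np.random.default_rng(0)
        t = 0.0
        for _ in range(200):
            t += float(rng.uniform(0.1, 20.0))
            result = est.update(bl.BreathEvent(t, PEAK, 1.0))
            if result.rate is not None:
                assert 4.0 <= result.rate <= 30.0


class TestProcessStream:
    def test_clean_constant_rate_recovered(self, clean_signal_factory):
        sig, _ = clean_signal_factory(6.0, 120.0)
        estimates = bl.process_stream(sig)
        post = [e for e in estimates if e.time >= 60.0]
        assert post and all(e.rate is not None for e in post)
        assert max(abs(e.rate - 6.0) for e in post) <= 0.5

    def test_one_estimate_per_tick(self, clean_signal_factory):
        sig, _ = clean_signal_factory(12.0, 30.0)
        estimates = bl.process_stream(sig, tick_rate=5.0)
        assert len(estimates) == 150
        assert np.allclose(np.diff([e.time for e in estimates]), 0.2)

    def test_causality_prefix_invariance(self, clean_signal_factory):
        """Estimates up to time t must not change when later samples differ."""
        sig, _ = clean_signal_factory(10.0, 60.0)
        half = bl.RespSignal(sig.sample_rate, sig.values[:300])
        full = bl.process_stream(sig)
        prefix = bl.process_stream(half)
        for a, b in zip(prefix, full[:len(prefix)]):
            assert a == b

    def test_convergence_slows_with_window_size(self):
        cfg = clean_config(18.0, 200.0)
        cfg = bl.SimConfig(**{**cfg.__dict__,
                              "rate_trajectory": bl.RateTrajectory.step(60.0, 18.0, 6.0)})
        times = []
        for w in (1, 3, 5):
            estimates = bl.process_stream(
                bl.make_breath_waveform(cfg)[0],
                estimator_params=bl.EstimatorParams(window_cycles=w))
            reached = None
            for e in estimates:
                if e.time < 60.0:
                    continue
                if e.rate is not None and abs(e.rate - 6.0) <= 0.5:
                    if reached is None:
                        reached = e.time
                else:
                    reached = None
            assert reached is not None
            times.append(reached)
        assert times[0] <= times[1] <= times[2]
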