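import pytest
from hypothesis import HealthCheck, settings

import breathloop as bl

settings.register_profile(
    "breathloop",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("breathloop")


def clean_config(rate: float, duration: float = 60.0, **kwargs) -> bl.SimConfig:
    """Constant-rate, jitter/noise/drift-free simulation recipe."""
    defaults = dict(
        duration=duration,
        rate_trajectory=bl.RateTrajectory.constant(rate),
        amplitude_jitter=0.0,
        cycle_jitter=0.0,
        drift_amplitude=0.0,
        noise_sd=0.0,
    )
    defaults.update(kwargs)
    return bl.SimConfig(**defaults)


@pytest.fixture
def clean_signal_factory():
    def make(rate: float, duration: float = 60.0, **kwargs):
        return bl.make_breath_waveform(clean_config(rate, duration, **kwargs))
    return make


def stream_events(signal: bl.RespSignal, params: bl.DetectorParams | None = None):
    """Run the streaming detector over a whole signal."""
    detector = bl.StreamingDetector(params)
    events: list[bl.BreathEvent] = []
    for t, v in zip(signal.times, signal.values):
        events.extend(detector.push(float(t), float(v)))
    return events


def pilot_summaries(design: bl.PilotDesign, session_config: bl.SessionConfig | None = None):
    """Full simulate -> run -> summarize chain for every session of a design."""
    base = session_config or bl.SessionConfig()
    summaries = []
    for s in bl.simulate_pilot(design):
        config = bl.SessionConfig(
            condition=s.condition,
            tick_rate=base.tick_rate,
            detector=base.detector,
            estimator=base.estimator,
            band=base.band,
            representation=base.representation,
            participant_id=s.participant_id,
            session_index=s.session_index,
        )
        summaries.append(bl.summarize_session(bl.run_session(s.signal, config)))
    return summaries


def synthetic_summaries(n_participants, rng, score_offset=0.0, rate_offset=0.0,
                        n_sessions=10, base_rate=12.0, base_score=0.55,
                        rate_sd=1.0, score_sd=0.08, participant_sd=1.0):
    """Summary-level generator: linear condition effects, clipping-free noise.

    Used for statistical checks of the bootstrap machinery where a
    closed-form true effect on either variable is needed.
    """
    rows = []
    for i in range(n_participants):
        b = rng.normal(0, participant_sd)
        for j in range(n_sessions):
            cond = bl.WITH_FEEDBACK if j % 2 == 0 else bl.WITHOUT_FEEDBACK
            w = cond == bl.WITH_FEEDBACK
            rows.append(dict(
                participant_id=f"P{i:02d}", session_index=j, condition=cond,
                mean_rate=base_rate + b + rate_offset * w + rng.normal(0, rate_sd),
                mean_score=base_score + score_offset * w + rng.normal(0, score_sd),
                time_in_band=0.5, n_ticks_used=100,
            ))
    import pandas as pd
    return pd.DataFrame(rows)
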