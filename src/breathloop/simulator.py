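"""Synthetic respiration-belt signals with known ground truth.

A respiration belt measures changes in torso circumference, so the clean
signal is a quasi-periodic oscillation with one inhalation peak and one
exhalation trough per breath.  Real recordings from a standing, moving user
additionally contain movement artifacts that overlap the fast-breathing
frequency band (roughly 0.3-1 Hz), slow baseline drift from belt slippage
and posture, and broadband sensor noise.  This module generates such
signals together with the exact breath timings (ground truth), which makes
it possible to measure estimator error instead of eyeballing it.

Breath waveform
---------------
Each breath is an asymmetric raised cosine: the signal rises from trough to
peak over ``inhale_fraction`` of the cycle (default 0.4) and falls back over
the remainder, giving the physiologically typical
exhalation-longer-than-inhalation shape.  Per-breath period and amplitude
can be jittered to emulate natural breath-to-breath variability.

Everything is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "WITH_FEEDBACK",
    "WITHOUT_FEEDBACK",
    "RespSignal",
    "RateTrajectory",
    "GroundTruth",
    "ArtifactConfig",
    "SimConfig",
    "LearningModel",
    "PilotDesign",
    "PilotSession",
    "make_breath_waveform",
    "add_artifacts",
    "simulate_pilot",
    "write_signal",
    "read_signal",
    "write_events",
    "read_events",
]

WITH_FEEDBACK = "with_feedback"
WITHOUT_FEEDBACK = "without_feedback"
CONDITIONS = (WITH_FEEDBACK, WITHOUT_FEEDBACK)


@dataclass(frozen=True)
class RespSignal:
    """A uniformly sampled single-channel belt trace.

    Amplitude is in arbitrary units: stretch belts are uncalibrated, only
    the shape of the oscillation carries information.
    """

    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be positive, got {self.sample_rate}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ConfigurationError("values must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("signal values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        """Total covered time span in seconds (n_samples / sample_rate)."""
        return self.values.size / self.sample_rate

    def __eq__(self, other):  # ndarray field breaks dataclass eq
        if not isinstance(other, RespSignal):
            return NotImplemented
        return (
            self.sample_rate == other.sample_rate
            and self.start_time == other.start_time
            and self.values.shape == other.values.shape
            and bool(np.all(self.values == other.values))
        )


@dataclass(frozen=True)
class RateTrajectory:
    """True breathing rate as a piecewise function of time (breaths/min).

    ``interp='previous'`` gives a step function (value held from each
    breakpoint), ``interp='linear'`` a piecewise-linear ramp.
    """

    times: np.ndarray
    rates: np.ndarray
    interp: str = "previous"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if times.ndim != 1 or times.size < 1 or times.shape != rates.shape:
            raise ConfigurationError("trajectory needs matching 1-D times and rates")
        if np.any(np.diff(times) <= 0):
            raise ConfigurationError("trajectory breakpoints must strictly increase")
        if times[0] != 0:
            raise ConfigurationError("trajectory must start at t = 0")
        if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
            raise ConfigurationError("all rates in the trajectory must be positive")
        if self.interp not in ("previous", "linear"):
            raise ConfigurationError(f"unknown interpolation {self.interp!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rates", rates)

    @classmethod
    def constant(cls, rate: float) -> "RateTrajectory":
        return cls(np.array([0.0]), np.array([float(rate)]))

    @classmethod
    def ramp(cls, rate_start: float, rate_end: float, duration: float) -> "RateTrajectory":
        """Linear ramp from rate_start at t=0 to rate_end at t=duration."""
        return cls(np.array([0.0, float(duration)]),
                   np.array([float(rate_start), float(rate_end)]), interp="linear")

    @classmethod
    def step(cls, t_switch: float, before: float, after: float) -> "RateTrajectory":
        return cls(np.array([0.0, float(t_switch)]),
                   np.array([float(before), float(after)]))

    @classmethod
    def piecewise(cls, times, rates, interp: str = "previous") -> "RateTrajectory":
        return cls(np.asarray(times, dtype=float), np.asarray(rates, dtype=float), interp)

    def rate_at(self, t):
        """Evaluate the true rate at time(s) t; constant beyond the last breakpoint."""
        t = np.asarray(t, dtype=float)
        if self.interp == "linear":
            out = np.interp(t, self.times, self.rates)
        else:
            idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
            out = self.rates[idx]
        return float(out) if out.ndim == 0 else out

    def __eq__(self, other):
        if not isinstance(other, RateTrajectory):
            return NotImplemented
        return (
            self.interp == other.interp
            and self.times.shape == other.times.shape
            and bool(np.all(self.times == other.times))
            and bool(np.all(self.rates == other.rates))
        )


@dataclass(frozen=True)
class GroundTruth:
    """Exact breath landmarks for a simulated signal.

    Peaks and troughs strictly alternate, starting with the trough that
    opens the first breath cycle.
    """

    peak_times: np.ndarray
    trough_times: np.ndarray
    trajectory: RateTrajectory

    def __post_init__(self):
        peaks = np.asarray(self.peak_times, dtype=float)
        troughs = np.asarray(self.trough_times, dtype=float)
        for name, arr in (("peak_times", peaks), ("trough_times", troughs)):
            if arr.ndim != 1 or (arr.size > 1 and np.any(np.diff(arr) <= 0)):
                raise ConfigurationError(f"{name} must be 1-D and strictly increasing")
        merged = self._interleave(peaks, troughs)
        kinds = merged[1]
        if any(kinds[i] == kinds[i + 1] for i in range(len(kinds) - 1)):
            raise ConfigurationError("peaks and troughs must strictly alternate")
        object.__setattr__(self, "peak_times", peaks)
        object.__setattr__(self, "trough_times", troughs)

    @staticmethod
    def _interleave(peaks, troughs):
        times = np.concatenate([peaks, troughs])
        kinds = ["peak"] * peaks.size + ["trough"] * troughs.size
        order = np.argsort(times, kind="stable")
        return times[order], [kinds[i] for i in order]

    def events(self) -> list[tuple[float, str]]:
        """All landmarks as a time-ordered list of (time_s, kind)."""
        times, kinds = self._interleave(self.peak_times, self.trough_times)
        return list(zip(times.tolist(), kinds))

    def rate_at(self, t):
        return self.trajectory.rate_at(t)

    @property
    def n_breaths(self) -> int:
        return int(self.peak_times.size)

    def __eq__(self, other):
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.trajectory == other.trajectory
            and self.peak_times.shape == other.peak_times.shape
            and bool(np.all(self.peak_times == other.peak_times))
            and self.trough_times.shape == other.trough_times.shape
            and bool(np.all(self.trough_times == other.trough_times))
        )


@dataclass(frozen=True)
class ArtifactConfig:
    """Additive movement-artifact bursts.

    Bursts are amplitude-modulated sinusoids whose frequency range overlaps
    fast breathing (defaults 0.3-1.0 Hz), which is exactly what makes them
    impossible to remove by plain band-pass filtering.  ``burst_amplitude``
    is a fraction of the signal's half peak-to-trough range.
    """

    burst_rate: float = 4.0           # bursts per minute (Poisson)
    burst_duration: tuple[float, float] = (0.5, 2.0)   # seconds, uniform
    burst_amplitude: float = 0.5      # fraction of breathing half-range
    burst_frequency: tuple[float, float] = (0.3, 1.0)  # Hz, uniform per burst

    def __post_init__(self):
        if self.burst_rate < 0 or self.burst_amplitude < 0:
            raise ConfigurationError("burst_rate and burst_amplitude must be non-negative")
        lo, hi = self.burst_duration
        if lo < 0 or hi < lo:
            raise ConfigurationError("burst_duration range must be 0 <= lo <= hi")
        flo, fhi = self.burst_frequency
        if flo < 0 or fhi < flo:
            raise ConfigurationError("burst_frequency range must be 0 <= lo <= hi")


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for one synthetic belt recording."""

    duration: float = 60.0
    sample_rate: float = 10.0
    rate_trajectory: RateTrajectory = field(default_factory=lambda: RateTrajectory.constant(12.0))
    amplitude: float = 1.0            # peak-to-trough range of a clean breath, a.u.
    amplitude_jitter: float = 0.1     # fractional per-breath amplitude perturbation
    cycle_jitter: float = 0.05        # fractional per-breath period perturbation
    inhale_fraction: float = 0.4      # fraction of the cycle spent inhaling
    drift_amplitude: float = 0.1      # slow baseline drift, a.u.
    noise_sd: float = 0.02            # white sensor noise, a.u.
    artifact: ArtifactConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if not self.sample_rate > 0:
            raise ConfigurationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.amplitude <= 0:
            raise ConfigurationError("amplitude must be positive")
        for name in ("amplitude_jitter", "cycle_jitter"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.inhale_fraction < 1:
            raise ConfigurationError("inhale_fraction must be in (0, 1)")
        if self.drift_amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("drift_amplitude and noise_sd must be non-negative")


def _breath_cycles(config: SimConfig, rng: np.random.Generator):
    """Sequential per-breath (start, period, amplitude) covering [0, duration]."""
    starts, periods, amps = [], [], []
    t = 0.0
    while t < config.duration:
        rate = config.rate_trajectory.rate_at(t)
        period = 60.0 / rate
        if config.cycle_jitter > 0:
            period *= 1.0 + config.cycle_jitter * rng.uniform(-1.0, 1.0)
        amp = config.amplitude
        if config.amplitude_jitter > 0:
            amp *= 1.0 + config.amplitude_jitter * rng.uniform(-1.0, 1.0)
        starts.append(t)
        periods.append(period)
        amps.append(amp)
        t += period
    return np.array(starts), np.array(periods), np.array(amps)


def make_breath_waveform(config: SimConfig) -> tuple[RespSignal, GroundTruth]:
    """Generate a belt signal and its exact breath landmarks.

    The noise-free component has exactly one peak and one trough per breath;
    drift, noise and (optionally) artifact bursts are added on top without
    changing the ground truth.  Identical config (including seed) gives
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    starts, periods, amps = _breath_cycles(config, rng)

    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    phase = (t - starts[idx]) / periods[idx]

    f = config.inhale_fraction
    inhale = phase < f
    shape = np.where(
        inhale,
        -0.5 * np.cos(np.pi * np.clip(phase, 0.0, f) / f),
        0.5 * np.cos(np.pi * (np.clip(phase, f, 1.0) - f) / (1.0 - f)),
    )
    values = amps[idx] * shape

    if config.drift_amplitude > 0:
        f_d = rng.uniform(0.005, 0.02)
        phi = rng.uniform(0, 2 * np.pi)
        values = values + config.drift_amplitude * np.sin(2 * np.pi * f_d * t + phi)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, n)

    in_span = starts < config.duration
    trough_times = starts[in_span]
    peak_times = (starts + config.inhale_fraction * periods)
    peak_times = peak_times[peak_times < config.duration]
    truth = GroundTruth(peak_times, trough_times, config.rate_trajectory)

    signal = RespSignal(config.sample_rate, values)
    if config.artifact is not None:
        art_seed = int(rng.integers(0, 2**31 - 1))
        signal = add_artifacts(signal, truth, config.artifact, art_seed)
    return signal, truth


def add_artifacts(signal: RespSignal, truth: GroundTruth,
                  art: ArtifactConfig, seed: int) -> RespSignal:
    """Overlay movement-artifact bursts on a signal; ground truth is unchanged.

    Burst count is Poisson in ``burst_rate`` × duration; onset, duration,
    carrier frequency and phase are drawn per burst, all reproducible from
    ``seed``.  With ``burst_amplitude == 0`` the signal is returned unchanged.
    """
    if art.burst_amplitude == 0 or art.burst_rate == 0:
        return RespSignal(signal.sample_rate, signal.values.copy(), signal.start_time)
    rng = np.random.default_rng(seed)
    duration = signal.duration
    n_bursts = rng.poisson(art.burst_rate * duration / 60.0)
    values = signal.values.copy()
    t = signal.times
    amp = art.burst_amplitude * float(np.ptp(values)) / 2.0
    for _ in range(n_bursts):
        onset = rng.uniform(0.0, duration)
        dur = rng.uniform(*art.burst_duration)
        freq = rng.uniform(*art.burst_frequency)
        phi = rng.uniform(0, 2 * np.pi)
        lo = np.searchsorted(t, onset)
        hi = np.searchsorted(t, onset + dur)
        if hi <= lo or dur == 0:
            continue
        tt = t[lo:hi]
        envelope = np.sin(np.pi * (tt - onset) / dur) ** 2  # Hann-shaped on/off
        values[lo:hi] += amp * envelope * np.sin(2 * np.pi * freq * tt + phi)
    return RespSignal(signal.sample_rate, values, signal.start_time)


# ---------------------------------------------------------------------------
# Pilot-style multi-session datasets


@dataclass(frozen=True)
class LearningModel:
    """Per-session true mean breathing rate under training.

    model rate(participant i, session j, condition c) =
        start_rate + b_i - per_session_drop * j - feedback_offset * [c == with_feedback]
    with b_i ~ Normal(0, participant_sd), floored at floor_rate.

    The linear drop across sessions emulates skill acquisition; the negative
    condition offset emulates the extra slowing achieved while feedback is
    active.  Defaults start above the 4-12 breaths/min target band (load
    elevates breathing) and end inside it by the final sessions.
    """

    start_rate: float = 18.0
    per_session_drop: float = 0.6
    feedback_offset: float = 2.0
    participant_sd: float = 1.2
    floor_rate: float = 4.0

    def __post_init__(self):
        if self.start_rate <= 0 or self.floor_rate <= 0:
            raise ConfigurationError("rates must be positive")
        if self.participant_sd < 0:
            raise ConfigurationError("participant_sd must be non-negative")


def _alternating_conditions(n_sessions: int) -> tuple[str, ...]:
    return tuple(WITH_FEEDBACK if j % 2 == 0 else WITHOUT_FEEDBACK for j in range(n_sessions))


@dataclass(frozen=True)
class PilotDesign:
    """Layout of a pilot study: participants × alternating-condition sessions.

    Defaults mirror a small field pilot: 9 participants, 10 sessions of about
    15 minutes each, alternating with/without biofeedback starting with.
    """

    n_participants: int = 9
    n_sessions: int = 10
    session_duration: float = 900.0
    conditions: tuple[str, ...] | None = None
    learning: LearningModel = field(default_factory=LearningModel)
    signal_template: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_sessions < 1:
            raise ConfigurationError("need at least one participant and one session")
        if self.session_duration <= 0:
            raise ConfigurationError("session_duration must be positive")
        conds = self.conditions
        if conds is None:
            conds = _alternating_conditions(self.n_sessions)
        conds = tuple(conds)
        if len(conds) != self.n_sessions:
            raise ConfigurationError(
                f"conditions has length {len(conds)}, expected n_sessions = {self.n_sessions}"
            )
        for c in conds:
            if c not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {c!r}")
        object.__setattr__(self, "conditions", conds)

    def model_rate(self, participant_effect: float, session_index: int, condition: str) -> float:
        m = self.learning
        rate = (m.start_rate + participant_effect
                - m.per_session_drop * session_index
                - (m.feedback_offset if condition == WITH_FEEDBACK else 0.0))
        return max(m.floor_rate, rate)

    def true_mean_difference(self) -> float:
        """Closed-form condition effect (with - without) on the model mean rate.

        Valid as long as the floor never binds: the participant effect then
        cancels within participant and the effect is
        -feedback_offset + per_session_drop * (mean idx without - mean idx with).
        """
        idx_with = [j for j, c in enumerate(self.conditions) if c == WITH_FEEDBACK]
        idx_without = [j for j, c in enumerate(self.conditions) if c == WITHOUT_FEEDBACK]
        if not idx_with or not idx_without:
            raise ConfigurationError("both conditions must occur in the design")
        m = self.learning
        return -m.feedback_offset + m.per_session_drop * (
            float(np.mean(idx_without)) - float(np.mean(idx_with))
        )


@dataclass(frozen=True)
class PilotSession:
    """One simulated session: labels, model-level truth, signal and landmarks."""

    participant_id: str
    session_index: int
    condition: str
    model_rate: float
    signal: RespSignal
    truth: GroundTruth


def simulate_pilot(design: PilotDesign) -> list[PilotSession]:
    """Simulate a whole pilot dataset (n_participants × n_sessions sessions).

    Per-session true mean rates follow the learning model exactly; each
    session's waveform seed derives deterministically from the design seed.
    """
    rng = np.random.default_rng(design.seed)
    effects = rng.normal(0.0, design.learning.participant_sd, design.n_participants)
    seeds = rng.integers(0, 2**31 - 1, size=(design.n_participants, design.n_sessions))

    sessions = []
    for i in range(design.n_participants):
        pid = f"P{i + 1:02d}"
        for j in range(design.n_sessions):
            condition = design.conditions[j]
            rate = design.model_rate(float(effects[i]), j, condition)
            config = replace(
                design.signal_template,
                duration=design.session_duration,
                rate_trajectory=RateTrajectory.constant(rate),
                seed=int(seeds[i, j]),
            )
            signal, truth = make_breath_waveform(config)
            sessions.append(PilotSession(pid, j, condition, rate, signal, truth))
    return sessions


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_signal(signal: RespSignal, path) -> None:
    """Write a signal as two-column delimited text: time_s,value."""
    times = signal.times
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(times.tolist(), signal.values.tolist()):
            fh.write(f"{t:.3f},{v!r}\n")


def read_signal(path) -> RespSignal:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise ConfigurationError(f"expected two columns in {path}")
    times, values = data[:, 0], data[:, 1]
    if times.size < 2:
        raise ConfigurationError("signal file needs at least two samples to infer sample rate")
    dt = np.diff(times)
    if np.any(np.abs(dt - dt[0]) > 5e-4 + 1e-9):
        raise ConfigurationError("signal file is not uniformly sampled")
    return RespSignal(1.0 / float(np.mean(dt)), values, float(times[0]))


def write_events(truth: GroundTruth, path) -> None:
    """Write ground-truth landmarks as delimited text: event_time_s,kind."""
    with open(path, "w") as fh:
        fh.write("event_time_s,kind\n")
        for t, kind in truth.events():
            fh.write(f"{t!r},{kind}\n")


def read_events(path) -> list[tuple[float, str]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "event_time_s,kind":
            raise ConfigurationError(f"unexpected header in {path}: {header.strip()!r}")
        for line in fh:
            t, kind = line.strip().split(",")
            out.append((float(t), kind))
    return out
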