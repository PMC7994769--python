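"""Online breath detection and instantaneous breathing-rate estimation.

The belt signal cannot be cleaned by frequency filtering alone because
movement artifacts share the fast-breathing band, so detection works on
signal morphology instead: an extremum candidate is accepted once the
signal has reversed direction by a configurable fraction of the recent
peak-to-trough range (prominence gating), and same-kind extrema closer
than a refractory interval are merged, keeping the more prominent one.
Events are confirmed retrospectively: the emitted event carries the
extremum's own time, while emission happens a bounded interval later
(at most ``rolling_window`` seconds).

The instantaneous breathing rate is the reciprocal of the temporal
difference between consecutive same-phase landmarks (trough-to-trough by
default).  Intervals implying a physiologically implausible rate are
rejected outright — this is the main artifact-rejection stage — and the
last ``window_cycles`` accepted intervals are averaged before inversion,
trading responsiveness for stability.

``detect_extrema_offline`` applies the identical acceptance rules
non-causally with an independently written code path (pandas time-window
rolling statistics plus a separate scan); it serves as the oracle for the
streaming detector.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StreamOrderError
from .simulator import RespSignal

__all__ = [
    "BreathEvent",
    "DetectorParams",
    "EstimatorParams",
    "RateEstimate",
    "StreamingDetector",
    "RateEstimator",
    "interval_to_rate",
    "detect_extrema_offline",
    "detect_extrema_arrays",
    "process_stream",
]

PEAK = "peak"
TROUGH = "trough"

_TIME_EPS = 1e-6  # slack on time comparisons; far below any sane sample spacing


@dataclass(frozen=True)
class BreathEvent:
    """A detected inhalation peak or exhalation trough."""

    time: float
    kind: str  # "peak" | "trough"
    amplitude: float


@dataclass(frozen=True)
class DetectorParams:
    """Tuning of the extremum detector.

    refractory
        Minimum spacing between same-kind events, seconds.  Closer pairs are
        merged, keeping the more prominent extremum.
    prominence_fraction
        Fraction of the rolling peak-to-trough range the signal must reverse
        by before a candidate extremum is confirmed.
    rolling_window
        Length of the causal window (seconds) over which that range is
        tracked; also the worst-case emission latency.
    """

    refractory: float = 1.0
    prominence_fraction: float = 0.3
    rolling_window: float = 20.0

    def __post_init__(self):
        if self.refractory <= 0:
            raise ConfigurationError("refractory must be positive")
        if not 0 < self.prominence_fraction < 1:
            raise ConfigurationError("prominence_fraction must be in (0, 1)")
        if self.rolling_window <= 0:
            raise ConfigurationError("rolling_window must be positive")
        if self.refractory > self.rolling_window:
            raise ConfigurationError("refractory must not exceed rolling_window")


@dataclass(frozen=True)
class EstimatorParams:
    """Tuning of the same-phase interval averager."""

    window_cycles: int = 3
    plausible_rate: tuple[float, float] = (2.0, 60.0)
    staleness_timeout: float = 15.0
    phase: str = TROUGH

    def __post_init__(self):
        if self.window_cycles < 1:
            raise ConfigurationError("window_cycles must be >= 1")
        lo, hi = self.plausible_rate
        if not 0 < lo < hi:
            raise ConfigurationError("plausible_rate must satisfy 0 < min < max")
        if self.staleness_timeout <= 0:
            raise ConfigurationError("staleness_timeout must be positive")
        if self.phase not in (PEAK, TROUGH):
            raise ConfigurationError(f"phase must be 'peak' or 'trough', got {self.phase!r}")


@dataclass(frozen=True)
class RateEstimate:
    """Instantaneous breathing rate in breaths/min; ``rate is None`` during warm-up."""

    time: float
    rate: float | None
    n_cycles: int
    stale: bool


def interval_to_rate(interval: float) -> float:
    """Convert a same-phase interval in seconds to breaths/min (60 / interval)."""
    if not interval > 0:
        raise ConfigurationError(f"interval must be positive, got {interval}")
    return 60.0 / interval


class StreamingDetector:
    """Causal extremum detector; one instance per sample stream.

    ``push(t, v)`` ingests one sample and returns the (possibly empty) list
    of breath events confirmed by it, in time order.  Event times refer to
    the extremum, not the moment of emission.
    """

    def __init__(self, params: DetectorParams | None = None):
        self.params = params or DetectorParams()
        self._last_t = -np.inf
        # rolling range over the trailing window: monotone deques of (t, v)
        self._maxq: deque = deque()
        self._minq: deque = deque()
        # state machine: 0 = warm-up (direction unknown), +1 rising, -1 falling
        self._mode = 0
        self._hi = None  # running max since start (warm-up only)
        self._lo = None  # running min since start (warm-up only)
        self._cand = None  # current extremum candidate (t, v)
        # confirmed but not yet emitted events, time-ordered: [t, v, kind]
        self._pending: deque = deque()
        self._last_emitted: dict[str, float] = {}

    # -- rolling range -----------------------------------------------------
    def _update_range(self, t: float, v: float) -> float:
        cutoff = t - self.params.rolling_window - _TIME_EPS
        for q in (self._maxq, self._minq):
            while q and q[0][0] < cutoff:
                q.popleft()
        while self._maxq and self._maxq[-1][1] <= v:
            self._maxq.pop()
        self._maxq.append((t, v))
        while self._minq and self._minq[-1][1] >= v:
            self._minq.pop()
        self._minq.append((t, v))
        return self.params.prominence_fraction * (self._maxq[0][1] - self._minq[0][1])

    # -- confirmation with refractory merging ------------------------------
    def _confirm(self, kind: str, tm: float, vm: float) -> None:
        pending = self._pending
        last_idx = None
        for i in range(len(pending) - 1, -1, -1):
            if pending[i][2] == kind:
                last_idx = i
                break
        last_t = pending[last_idx][0] if last_idx is not None else self._last_emitted.get(kind)

        if last_t is not None and tm - last_t < self.params.refractory:
            if last_idx is not None:
                # merge with the still-pending rival: keep the more prominent,
                # drop the shallow opposite extremum between them
                rival = pending[last_idx]
                better = vm > rival[1] if kind == PEAK else vm < rival[1]
                if better:
                    pending[last_idx] = [tm, vm, kind]
                while len(pending) > last_idx + 1:
                    pending.pop()
            elif pending and pending[-1][2] != kind:
                # rival already emitted; drop the newcomer and the pending
                # opposite between them so emitted kinds keep alternating
                pending.pop()
            else:
                # rival and the intervening opposite were both already emitted
                # (needs a confirmation delayed beyond rolling_window, which
                # band-limited breathing plus bursts does not produce); keep
                # the newcomer so alternation survives at refractory's expense
                pending.append([tm, vm, kind])
        else:
            pending.append([tm, vm, kind])

    def _emit_ready(self, now: float, out: list) -> None:
        p = self.params
        while self._pending:
            t0, v0, k0 = self._pending[0]
            if now - t0 <= p.refractory:
                break
            # A same-kind rival that could still merge with this event must
            # have an extremum time < t0 + refractory, i.e. it can only be
            # the current candidate if that candidate is of the same kind
            # and sits before the refractory horizon.  Hold until that
            # possibility is gone (or a hard latency bound is reached).
            heading = PEAK if self._mode == 1 else TROUGH if self._mode == -1 else None
            rival_possible = (heading == k0 and self._cand is not None
                              and self._cand[0] < t0 + p.refractory)
            if rival_possible and now - t0 <= p.rolling_window:
                break
            out.append(BreathEvent(t0, k0, v0))
            self._last_emitted[k0] = t0
            self._pending.popleft()

    # -- public ------------------------------------------------------------
    def push(self, t: float, v: float) -> list[BreathEvent]:
        if t <= self._last_t:
            raise StreamOrderError(f"sample at t={t} not after previous t={self._last_t}")
        self._last_t = t
        theta = self._update_range(t, v)
        out: list[BreathEvent] = []

        if self._mode == 0:
            if self._hi is None or v > self._hi[1]:
                self._hi = (t, v)
            if self._lo is None or v < self._lo[1]:
                self._lo = (t, v)
            if theta > 0 and v < self._hi[1] - theta:
                self._confirm(PEAK, *self._hi)
                self._mode, self._cand = -1, (t, v)
            elif theta > 0 and v > self._lo[1] + theta:
                self._confirm(TROUGH, *self._lo)
                self._mode, self._cand = 1, (t, v)
        elif self._mode == 1:  # rising: candidate is a peak
            if v > self._cand[1]:
                self._cand = (t, v)
            elif theta > 0 and v < self._cand[1] - theta:
                self._confirm(PEAK, *self._cand)
                self._mode, self._cand = -1, (t, v)
        else:  # falling: candidate is a trough
            if v < self._cand[1]:
                self._cand = (t, v)
            elif theta > 0 and v > self._cand[1] + theta:
                self._confirm(TROUGH, *self._cand)
                self._mode, self._cand = 1, (t, v)

        self._emit_ready(t, out)
        return out


def detect_extrema_arrays(times: np.ndarray, values: np.ndarray,
                          params: DetectorParams | None = None) -> list[BreathEvent]:
    """Batch extremum detection on raw (times, values) arrays.

    Applies the streaming detector's acceptance rules non-causally: the
    rolling range is computed with pandas time-window rolling statistics and
    a single left-to-right scan confirms and merges extrema with the whole
    record available, so no emission gating is needed.  Mid-signal output
    matches the streaming detector exactly; events the stream would still be
    holding at the end of data (within one rolling_window of it) are
    included here.
    """
    params = params or DetectorParams()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = times.size
    if n == 0:
        return []
    if n > 1 and np.any(np.diff(times) <= 0):
        raise StreamOrderError("times must strictly increase")

    index = pd.to_timedelta(times, unit="s")
    series = pd.Series(values, index=index)
    window = pd.Timedelta(seconds=params.rolling_window + _TIME_EPS)
    rmax = series.rolling(window, closed="both", min_periods=1).max().to_numpy()
    rmin = series.rolling(window, closed="both", min_periods=1).min().to_numpy()
    theta = params.prominence_fraction * (rmax - rmin)

    events: list[list] = []  # [t, v, kind], merged in place

    def confirm(kind: str, tm: float, vm: float) -> None:
        last_idx = None
        for i in range(len(events) - 1, -1, -1):
            if events[i][2] == kind:
                last_idx = i
                break
        if last_idx is not None and tm - events[last_idx][0] < params.refractory:
            rival = events[last_idx]
            if (vm > rival[1]) if kind == PEAK else (vm < rival[1]):
                events[last_idx] = [tm, vm, kind]
            del events[last_idx + 1:]
        else:
            events.append([tm, vm, kind])

    mode = 0
    hi = lo = cand = None
    for i in range(n):
        t, v, th = times[i], values[i], theta[i]
        if mode == 0:
            if hi is None or v > hi[1]:
                hi = (t, v)
            if lo is None or v < lo[1]:
                lo = (t, v)
            if th > 0 and v < hi[1] - th:
                confirm(PEAK, *hi)
                mode, cand = -1, (t, v)
            elif th > 0 and v > lo[1] + th:
                confirm(TROUGH, *lo)
                mode, cand = 1, (t, v)
        elif mode == 1:
            if v > cand[1]:
                cand = (t, v)
            elif th > 0 and v < cand[1] - th:
                confirm(PEAK, *cand)
                mode, cand = -1, (t, v)
        else:
            if v < cand[1]:
                cand = (t, v)
            elif th > 0 and v > cand[1] + th:
                confirm(TROUGH, *cand)
                mode, cand = 1, (t, v)

    return [BreathEvent(t, kind, v) for t, v, kind in events]


def detect_extrema_offline(signal: RespSignal,
                           params: DetectorParams | None = None) -> list[BreathEvent]:
    """Batch oracle for the streaming detector (see detect_extrema_arrays)."""
    return detect_extrema_arrays(signal.times, signal.values, params)


class RateEstimator:
    """Same-phase interval averager with plausibility-based artifact rejection."""

    def __init__(self, params: EstimatorParams | None = None):
        self.params = params or EstimatorParams()
        self._intervals: deque = deque(maxlen=self.params.window_cycles)
        self._prev_t: float | None = None
        self._rate: float | None = None
        self._last_accept: float | None = None
        self._last_event_t = -np.inf

    def update(self, event: BreathEvent) -> RateEstimate | None:
        """Ingest one breath event; returns the refreshed estimate for
        same-phase events, None otherwise.  Implausible intervals are
        rejected silently, but the same-phase anchor still advances."""
        if event.time < self._last_event_t:
            raise StreamOrderError(
                f"event at t={event.time} before previous t={self._last_event_t}")
        self._last_event_t = event.time
        if event.kind != self.params.phase:
            return None
        if self._prev_t is not None:
            interval = event.time - self._prev_t
            lo, hi = self.params.plausible_rate
            if interval > 0 and lo <= 60.0 / interval <= hi:
                self._intervals.append(interval)
                self._rate = 60.0 / (sum(self._intervals) / len(self._intervals))
                self._last_accept = event.time
        self._prev_t = event.time
        return self.estimate_at(event.time)

    def estimate_at(self, t: float) -> RateEstimate:
        """Current estimate as of time t (rate held between events)."""
        stale = (self._last_accept is not None
                 and t - self._last_accept > self.params.staleness_timeout)
        return RateEstimate(t, self._rate, len(self._intervals), stale)


def process_stream(signal: RespSignal,
                   detector_params: DetectorParams | None = None,
                   estimator_params: EstimatorParams | None = None,
                   tick_rate: float = 10.0) -> list[RateEstimate]:
    """Run detector and estimator over a signal, emitting one estimate per tick.

    The latest estimate is held between breath events.  Causal by
    construction: the estimate at tick time t only sees samples with
    time <= t.
    """
    if tick_rate <= 0:
        raise ConfigurationError("tick_rate must be positive")
    detector = StreamingDetector(detector_params)
    estimator = RateEstimator(estimator_params)

    n_ticks = int(round(signal.duration * tick_rate))
    ticks = signal.start_time + np.arange(n_ticks) / tick_rate
    out: list[RateEstimate] = []
    ti = 0
    for t, v in zip(signal.times, signal.values):
        while ti < n_ticks and ticks[ti] < t - _TIME_EPS:
            out.append(estimator.estimate_at(float(ticks[ti])))
            ti += 1
        for event in detector.push(float(t), float(v)):
            estimator.update(event)
        while ti < n_ticks and ticks[ti] <= t + _TIME_EPS:
            out.append(estimator.estimate_at(float(ticks[ti])))
            ti += 1
    while ti < n_ticks:
        out.append(estimator.estimate_at(float(ticks[ti])))
        ti += 1
    return out
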