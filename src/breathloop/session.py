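"""Closed-loop session orchestration and reproducible session logs.

``run_session`` chains detector -> estimator -> score -> smoothing ->
representation at a fixed tick rate.  In the control condition
(``without_feedback``) the score is still computed and logged — so both
conditions are directly comparable in analysis — but the representation is
frozen fully open (aperture 1.0, light 1.0) and never affects the
environment.

Logs are diff-friendly delimited text: a ``#``-prefixed key=value block
echoing the full configuration, one column-header row, then one row per
tick.  Timestamps are written with 3-decimal precision; all other values
are written with shortest round-trip float formatting, which is what makes
``replay`` able to check a stored log bit-for-bit against recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LogParseError, LogValidationError
from .feedback import RepresentationParams, TargetBand, compute_score, smooth
from .realtime import DetectorParams, EstimatorParams, RateEstimator, StreamingDetector
from .simulator import CONDITIONS, WITH_FEEDBACK, RespSignal

__all__ = [
    "SessionConfig",
    "SessionRecord",
    "ReplayReport",
    "run_session",
    "write_session",
    "read_session",
    "replay",
    "config_to_mapping",
    "config_from_mapping",
]

COLUMNS = ["time", "raw", "rate", "score", "aperture", "light", "stale"]
_TICK_TOL = 5.1e-4  # written timestamps carry 3 decimals


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to (re)run one session deterministically."""

    condition: str = WITH_FEEDBACK
    tick_rate: float = 10.0
    detector: DetectorParams = field(default_factory=DetectorParams)
    estimator: EstimatorParams = field(default_factory=EstimatorParams)
    band: TargetBand = field(default_factory=TargetBand)
    representation: RepresentationParams = field(default_factory=RepresentationParams)
    participant_id: str = "P00"
    session_index: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if not self.tick_rate > 0:
            raise ConfigurationError("tick_rate must be positive")


@dataclass
class SessionRecord:
    """One session's config echo plus the tick-level log as a DataFrame."""

    config: SessionConfig
    frame: pd.DataFrame

    def __eq__(self, other):
        if not isinstance(other, SessionRecord):
            return NotImplemented
        if self.config != other.config:
            return False
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not np.allclose(a["time"], b["time"], rtol=0.0, atol=_TICK_TOL):
            return False
        for col in COLUMNS[1:]:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if not np.array_equal(x, y, equal_nan=(x.dtype.kind == "f")):
                return False
        return True


def _zero_order_hold(signal: RespSignal, tick_times: np.ndarray) -> np.ndarray:
    """Raw value consumed at each tick: last sample at or before the tick."""
    rel = (tick_times - signal.start_time) * signal.sample_rate
    idx = np.clip(np.floor(rel + 1e-9).astype(int), 0, signal.values.size - 1)
    return signal.values[idx]


def run_session(signal: RespSignal, config: SessionConfig,
                flush_path=None) -> SessionRecord:
    """Run the closed loop over a signal; pure function of (signal, config).

    Samples are consumed at the tick cadence (zero-order hold), so a stored
    log's raw column is sufficient to reproduce every derived column.  If
    ``flush_path`` is given and the stream errors mid-run, the partial
    record is written there before the error propagates.
    """
    n_ticks = int(round(signal.duration * config.tick_rate))
    if n_ticks < 1:
        raise ConfigurationError("signal shorter than one tick")
    dt = 1.0 / config.tick_rate
    tick_times = np.arange(n_ticks) / config.tick_rate
    raw = _zero_order_hold(signal, tick_times)

    detector = StreamingDetector(config.detector)
    estimator = RateEstimator(config.estimator)
    band = config.band
    rep = config.representation
    with_fb = config.condition == WITH_FEEDBACK

    rates = np.full(n_ticks, np.nan)
    scores = np.empty(n_ticks)
    apertures = np.empty(n_ticks)
    lights = np.empty(n_ticks)
    stales = np.zeros(n_ticks, dtype=int)

    smoothed = rep.neutral_score
    last_rate, last_score = None, rep.neutral_score
    k = 0
    try:
        for k in range(n_ticks):
            t = float(tick_times[k])
            for event in detector.push(t, float(raw[k])):
                estimator.update(event)
            est = estimator.estimate_at(t)
            if est.rate != last_rate:
                last_rate = est.rate
                last_score = compute_score(est.rate, band, rep.neutral_score)
            smoothed = smooth(smoothed, last_score, dt, rep.smoothing_time)
            if est.rate is not None:
                rates[k] = est.rate
            scores[k] = last_score
            stales[k] = int(est.stale)
            if with_fb:
                apertures[k] = rep.floor + smoothed * (1.0 - rep.floor)
                lights[k] = rep.min_light + smoothed * (1.0 - rep.min_light)
            else:
                apertures[k] = 1.0
                lights[k] = 1.0
    except Exception:
        if flush_path is not None:
            partial = _assemble(config, tick_times[:k], raw[:k], rates[:k],
                                scores[:k], apertures[:k], lights[:k], stales[:k])
            write_session(partial, flush_path)
        raise

    return _assemble(config, tick_times, raw, rates, scores, apertures, lights, stales)


def _assemble(config, times, raw, rates, scores, apertures, lights, stales):
    frame = pd.DataFrame({
        "time": times, "raw": raw, "rate": rates, "score": scores,
        "aperture": apertures, "light": lights, "stale": stales,
    })
    return SessionRecord(config=config, frame=frame)


# ---------------------------------------------------------------------------
# Flat key=value (de)serialization of the config


def config_to_mapping(config: SessionConfig) -> dict[str, str]:
    d, e, b, r = config.detector, config.estimator, config.band, config.representation
    return {
        "condition": config.condition,
        "tick_rate": repr(config.tick_rate),
        "participant_id": config.participant_id,
        "session_index": str(config.session_index),
        "detector.refractory": repr(d.refractory),
        "detector.prominence_fraction": repr(d.prominence_fraction),
        "detector.rolling_window": repr(d.rolling_window),
        "estimator.window_cycles": str(e.window_cycles),
        "estimator.plausible_low": repr(e.plausible_rate[0]),
        "estimator.plausible_high": repr(e.plausible_rate[1]),
        "estimator.staleness_timeout": repr(e.staleness_timeout),
        "estimator.phase": e.phase,
        "band.low": repr(b.low),
        "band.high": repr(b.high),
        "band.zero_low": repr(b.zero_low),
        "band.zero_high": repr(b.zero_high),
        "representation.floor": repr(r.floor),
        "representation.min_light": repr(r.min_light),
        "representation.smoothing_time": repr(r.smoothing_time),
        "representation.neutral_score": repr(r.neutral_score),
    }


def config_from_mapping(mapping: dict[str, str],
                        overrides: dict[str, str] | None = None) -> SessionConfig:
    """Build a SessionConfig from flat key=value strings (CLI/config-file form)."""
    m = dict(config_to_mapping(SessionConfig()))
    for src in (mapping, overrides or {}):
        for key, value in src.items():
            if key not in m:
                raise ConfigurationError(f"unknown session config key {key!r}")
            m[key] = str(value)
    try:
        return SessionConfig(
            condition=m["condition"],
            tick_rate=float(m["tick_rate"]),
            participant_id=m["participant_id"],
            session_index=int(m["session_index"]),
            detector=DetectorParams(
                refractory=float(m["detector.refractory"]),
                prominence_fraction=float(m["detector.prominence_fraction"]),
                rolling_window=float(m["detector.rolling_window"]),
            ),
            estimator=EstimatorParams(
                window_cycles=int(m["estimator.window_cycles"]),
                plausible_rate=(float(m["estimator.plausible_low"]),
                                float(m["estimator.plausible_high"])),
                staleness_timeout=float(m["estimator.staleness_timeout"]),
                phase=m["estimator.phase"],
            ),
            band=TargetBand(
                low=float(m["band.low"]), high=float(m["band.high"]),
                zero_low=float(m["band.zero_low"]), zero_high=float(m["band.zero_high"]),
            ),
            representation=RepresentationParams(
                floor=float(m["representation.floor"]),
                min_light=float(m["representation.min_light"]),
                smoothing_time=float(m["representation.smoothing_time"]),
                neutral_score=float(m["representation.neutral_score"]),
            ),
        )
    except ValueError as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Log I/O


def write_session(record: SessionRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("# breathloop session log v1\n")
        for key, value in config_to_mapping(record.config).items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(COLUMNS) + "\n")
        for row in record.frame.itertuples(index=False):
            rate = "" if math.isnan(row.rate) else repr(row.rate)
            fh.write(
                f"{row.time:.3f},{row.raw!r},{rate},{row.score!r},"
                f"{row.aperture!r},{row.light!r},{int(row.stale)}\n"
            )


def read_session(path) -> SessionRecord:
    mapping: dict[str, str] = {}
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    mapping[key.strip()] = value.strip()
                continue
            parts = line.split(",")
            if not header_seen:
                if parts != COLUMNS:
                    raise LogParseError(
                        f"expected column header {','.join(COLUMNS)!r}, got {line!r}", lineno)
                header_seen = True
                continue
            if len(parts) != len(COLUMNS):
                raise LogParseError(
                    f"expected {len(COLUMNS)} columns, got {len(parts)}", lineno)
            try:
                rows.append((
                    float(parts[0]), float(parts[1]),
                    float(parts[2]) if parts[2] != "" else np.nan,
                    float(parts[3]), float(parts[4]), float(parts[5]), int(parts[6]),
                ))
            except ValueError as exc:
                raise LogParseError(str(exc), lineno) from exc
    if not header_seen:
        raise LogParseError("no column header found")
    if not rows:
        raise LogParseError("log contains no data rows")

    config = config_from_mapping(mapping)
    frame = pd.DataFrame(rows, columns=COLUMNS)
    times = frame["time"].to_numpy()
    expected = np.arange(len(frame)) / config.tick_rate + times[0]
    if np.any(np.abs(times - expected) > _TICK_TOL):
        bad = int(np.argmax(np.abs(times - expected) > _TICK_TOL))
        raise LogValidationError(
            f"tick spacing violated at row {bad}: time {times[bad]} != {expected[bad]:.3f}")
    return SessionRecord(config=config, frame=frame)


@dataclass
class ReplayReport:
    """Outcome of recomputing a stored log's derived columns from its raw column."""

    record: SessionRecord
    recomputed: SessionRecord
    mismatches: pd.DataFrame  # columns: row, column, stored, recomputed

    @property
    def ok(self) -> bool:
        return self.mismatches.empty


def replay(path, overrides: dict[str, str] | None = None) -> ReplayReport:
    """Re-derive every derived column of a stored log and report mismatches.

    With ``overrides`` (e.g. a different target band) the mismatches show
    exactly which columns the changed parameters touch.
    """
    record = read_session(path)
    config = (config_from_mapping(config_to_mapping(record.config), overrides)
              if overrides else record.config)
    signal = RespSignal(config.tick_rate, record.frame["raw"].to_numpy(),
                        float(record.frame["time"].iloc[0]))
    recomputed = run_session(signal, config)

    mismatches = []
    for col in ("rate", "score", "aperture", "light", "stale"):
        a = record.frame[col].to_numpy()
        b = recomputed.frame[col].to_numpy()
        if a.dtype.kind == "f":
            diff = ~((a == b) | (np.isnan(a) & np.isnan(b)))
        else:
            diff = a != b
        for i in np.flatnonzero(diff):
            mismatches.append((int(i), col, a[i], b[i]))
    report = pd.DataFrame(mismatches, columns=["row", "column", "stored", "recomputed"])
    return ReplayReport(record=record, recomputed=recomputed, mismatches=report)
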