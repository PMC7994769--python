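"""Biofeedback score and its sensory representation.

The score quantifies how well the current breathing rate matches the
slow-breathing target band (default 4-12 breaths/min): it is a trapezoid in
rate — 1 everywhere on the closed band, descending linearly to 0 at
``zero_low`` below and ``zero_high`` above, and 0 beyond.  The plateau
rewards the whole band rather than a single rate, which keeps artifact- and
physiology-induced variability from constantly toggling the feedback, while
the ramps still give graded guidance outside the band.

The representation maps the (exponentially smoothed) score onto a
tunnel-vision aperture and an environmental light level.  Both mappings are
affine with a strictly positive floor: even at the worst score the trainee
keeps a minimum of peripheral visibility and light, so they can still
function in the environment.  During warm-up, before any rate estimate
exists, a neutral score (default 0.5) is used instead of the worst one so a
session never opens at maximum tunnel vision.

A cosine-eased pacer waveform is provided for guided-breathing tutorials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TargetBand",
    "RepresentationParams",
    "ScoreSample",
    "RepresentationState",
    "compute_score",
    "smooth",
    "score_to_aperture",
    "score_to_light",
    "pacer_position",
]


@dataclass(frozen=True)
class TargetBand:
    """Target band in breaths/min with the outer rates where the score bottoms out."""

    low: float = 4.0
    high: float = 12.0
    zero_low: float = 1.0
    zero_high: float = 24.0

    def __post_init__(self):
        if not self.zero_low <= self.low < self.high <= self.zero_high:
            raise ConfigurationError(
                f"need zero_low <= low < high <= zero_high, got "
                f"{self.zero_low}, {self.low}, {self.high}, {self.zero_high}"
            )


@dataclass(frozen=True)
class RepresentationParams:
    """Mapping from score to aperture/light, plus smoothing and warm-up behavior."""

    floor: float = 0.25          # minimum aperture fraction (never fully blind)
    min_light: float = 0.3       # minimum environmental light level
    smoothing_time: float = 2.0  # exponential time constant for the feedback, seconds
    neutral_score: float = 0.5   # score assumed while no rate estimate exists

    def __post_init__(self):
        for name in ("floor", "min_light"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.smoothing_time < 0:
            raise ConfigurationError("smoothing_time must be >= 0")
        if not 0 <= self.neutral_score <= 1:
            raise ConfigurationError("neutral_score must be in [0, 1]")


@dataclass(frozen=True)
class ScoreSample:
    time: float
    score: float


@dataclass(frozen=True)
class RepresentationState:
    aperture: float
    light_level: float


def compute_score(rate, band: TargetBand | None = None, neutral: float = 0.5):
    """Trapezoid biofeedback score in [0, 1] for a breathing rate.

    1.0 on the closed band [low, high]; linear to 0 at zero_low/zero_high;
    0 beyond.  ``rate=None`` (or NaN) — no estimate yet — returns ``neutral``.
    Accepts scalars or arrays (NaN entries map to ``neutral``).
    """
    band = band or TargetBand()
    if rate is None:
        return neutral
    r = np.asarray(rate, dtype=float)
    # ramps evaluate to >= 1 inside the band, so min() selects the right side
    if band.low > band.zero_low:
        below = (r - band.zero_low) / (band.low - band.zero_low)
    else:
        below = np.where(r >= band.low, 1.0, 0.0)
    if band.zero_high > band.high:
        above = (band.zero_high - r) / (band.zero_high - band.high)
    else:
        above = np.where(r <= band.high, 1.0, 0.0)
    score = np.clip(np.minimum(below, above), 0.0, 1.0)
    score = np.where(np.isnan(r), neutral, score)
    return float(score) if score.ndim == 0 else score


def smooth(previous: float, target: float, dt: float, smoothing_time: float) -> float:
    """Exponential approach from ``previous`` toward ``target`` over ``dt`` seconds.

    A contraction in both arguments; returns ``target`` exactly when
    ``smoothing_time`` is 0.
    """
    if dt < 0:
        raise ConfigurationError("dt must be >= 0")
    if smoothing_time <= 0:
        return target
    return previous + (target - previous) * (1.0 - float(np.exp(-dt / smoothing_time)))


def score_to_aperture(score, params: RepresentationParams | None = None):
    """Fraction of the full peripheral field: floor + score * (1 - floor)."""
    params = params or RepresentationParams()
    s = np.asarray(score, dtype=float)
    out = params.floor + s * (1.0 - params.floor)
    return float(out) if out.ndim == 0 else out


def score_to_light(score, params: RepresentationParams | None = None):
    """Environmental light level: min_light + score * (1 - min_light)."""
    params = params or RepresentationParams()
    s = np.asarray(score, dtype=float)
    out = params.min_light + s * (1.0 - params.min_light)
    return float(out) if out.ndim == 0 else out


def pacer_position(t, rate: float, inhale_fraction: float = 0.4):
    """Visual pacer position in [0, 1] at time(s) t for a paced rate.

    One cycle lasts 60/rate seconds: the position rises 0 -> 1 over the
    inhale segment and falls 1 -> 0 over the exhale segment, each with
    cosine easing, so the waveform is continuous across segment boundaries.
    """
    if not rate > 0:
        raise ConfigurationError(f"pacer rate must be positive, got {rate}")
    if not 0 < inhale_fraction < 1:
        raise ConfigurationError("inhale_fraction must be in (0, 1)")
    period = 60.0 / rate
    phase = np.mod(np.asarray(t, dtype=float), period) / period
    f = inhale_fraction
    pos = np.where(
        phase < f,
        0.5 * (1.0 - np.cos(np.pi * np.clip(phase, 0.0, f) / f)),
        0.5 * (1.0 + np.cos(np.pi * (np.clip(phase, f, 1.0) - f) / (1.0 - f))),
    )
    return float(pos) if pos.ndim == 0 else pos
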