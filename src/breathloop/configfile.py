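"""Flat key=value config files and CLI ``--set`` overrides.

The format is deliberately minimal and human-editable: one ``key=value``
per line, ``#`` comments, dotted keys for nested parameter groups.  Every
documented default is overridable this way — this replaces a live tuning
dashboard with a reproducible, diffable mechanism.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .simulator import ArtifactConfig, RateTrajectory, SimConfig

__all__ = ["load_kv", "parse_overrides", "sim_config_from_mapping"]


def load_kv(path) -> dict[str, str]:
    """Read a flat key=value file; later keys win."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if "=" not in body:
                raise ConfigurationError(f"{path}: line {lineno}: expected key=value, got {body!r}")
            key, _, value = body.partition("=")
            mapping[key.strip()] = value.strip()
    return mapping


def parse_overrides(pairs) -> dict[str, str]:
    """Parse repeated ``--set key=value`` CLI arguments."""
    out: dict[str, str] = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigurationError(f"override must be key=value, got {pair!r}")
        key, _, value = pair.partition("=")
        out[key.strip()] = value.strip()
    return out


_SIM_FLOAT_KEYS = {
    "duration", "sample_rate", "amplitude", "amplitude_jitter", "cycle_jitter",
    "inhale_fraction", "drift_amplitude", "noise_sd",
    "rate", "rate_end", "step_time", "rate_after",
    "artifact.burst_rate", "artifact.burst_amplitude",
    "artifact.burst_duration_min", "artifact.burst_duration_max",
    "artifact.burst_freq_min", "artifact.burst_freq_max",
}


def sim_config_from_mapping(mapping: dict[str, str],
                            overrides: dict[str, str] | None = None,
                            seed: int | None = None) -> SimConfig:
    """Build a SimConfig from flat keys.

    The rate trajectory is given by ``rate`` (constant), plus optionally
    either ``rate_end`` (linear ramp over the duration) or ``step_time`` +
    ``rate_after`` (step change).
    """
    m: dict[str, str] = {}
    for src in (mapping, overrides or {}):
        for key, value in src.items():
            if key not in _SIM_FLOAT_KEYS and key != "seed":
                raise ConfigurationError(f"unknown simulation config key {key!r}")
            m[key] = str(value)

    def fget(key: str, default: float) -> float:
        try:
            return float(m.get(key, default))
        except ValueError as exc:
            raise ConfigurationError(f"bad value for {key!r}: {m[key]!r}") from exc

    duration = fget("duration", 60.0)
    rate = fget("rate", 12.0)
    if "rate_end" in m and "rate_after" in m:
        raise ConfigurationError("give either rate_end (ramp) or rate_after (step), not both")
    if "rate_end" in m:
        trajectory = RateTrajectory.ramp(rate, fget("rate_end", rate), duration)
    elif "rate_after" in m:
        if "step_time" not in m:
            raise ConfigurationError("rate_after requires step_time")
        trajectory = RateTrajectory.step(fget("step_time", 0.0), rate, fget("rate_after", rate))
    else:
        trajectory = RateTrajectory.constant(rate)

    artifact = None
    if any(k.startswith("artifact.") for k in m):
        artifact = ArtifactConfig(
            burst_rate=fget("artifact.burst_rate", 4.0),
            burst_duration=(fget("artifact.burst_duration_min", 0.5),
                            fget("artifact.burst_duration_max", 2.0)),
            burst_amplitude=fget("artifact.burst_amplitude", 0.5),
            burst_frequency=(fget("artifact.burst_freq_min", 0.3),
                             fget("artifact.burst_freq_max", 1.0)),
        )

    if seed is None:
        seed = int(m.get("seed", 0))
    return SimConfig(
        duration=duration,
        sample_rate=fget("sample_rate", 10.0),
        rate_trajectory=trajectory,
        amplitude=fget("amplitude", 1.0),
        amplitude_jitter=fget("amplitude_jitter", 0.1),
        cycle_jitter=fget("cycle_jitter", 0.05),
        inhale_fraction=fget("inhale_fraction", 0.4),
        drift_amplitude=fget("drift_amplitude", 0.1),
        noise_sd=fget("noise_sd", 0.02),
        artifact=artifact,
        seed=seed,
    )
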