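"""Generate a synthetic respiration-belt recording with known breath timings.

The simulated trainee breathes at 18 breaths/min under load and slows to
6 breaths/min over two minutes; movement artifacts overlap the
fast-breathing band, exactly the regime that defeats plain band-pass
filtering.
"""

import breathloop as bl

config = bl.SimConfig(
    duration=120.0,
    rate_trajectory=bl.RateTrajectory.ramp(18.0, 6.0, 120.0),
    artifact=bl.ArtifactConfig(burst_rate=4.0, burst_amplitude=0.5),
    seed=7,
)
signal, truth = bl.make_breath_waveform(config)

print(f"samples: {signal.values.size} at {signal.sample_rate:g} Hz "
      f"({signal.duration:.0f} s)")
print(f"breaths: {truth.n_breaths} "
      f"(first peak at {truth.peak_times[0]:.2f} s, last at {truth.peak_times[-1]:.2f} s)")
print(f"true rate: {truth.rate_at(0.0):.1f} breaths/min at start, "
      f"{truth.rate_at(120.0):.1f} at the end")
# Breath count ~ the time integral of the rate: (18+6)/2 bpm * 2 min = 24.
bl.write_signal(signal, "belt_signal.csv")
print("wrote belt_signal.csv (time_s,value) — amplitudes are unitless, "
      "belts are uncalibrated")
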