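"""Simulate and analyze a pilot-style training study.

Nine participants, ten alternating-condition sessions with a learning
trend: session means of breathing rate fall across training, the feedback
condition breathes slower, and session mean score relates quadratically to
session mean rate.  Sessions are shortened to two minutes here to keep the
example quick; the structure is what matters.
"""

import breathloop as bl

design = bl.PilotDesign(session_duration=120.0, seed=4)
sessions = bl.simulate_pilot(design)
print(f"{len(sessions)} sessions from {design.n_participants} participants")

summaries = []
for s in sessions:
    config = bl.SessionConfig(condition=s.condition, participant_id=s.participant_id,
                              session_index=s.session_index)
    summaries.append(bl.summarize_session(bl.run_session(s.signal, config)))
frame = bl.summaries_frame(summaries)

trends = bl.session_trends(frame)
group = trends[trends["level"] == "group"].groupby("session_index")["mean_rate"].mean()
print(f"group mean rate: {group.iloc[0]:.1f} breaths/min in session 0 "
      f"-> {group.iloc[-1]:.1f} in session {int(group.index[-1])}")

for variable in ("mean_rate", "mean_score"):
    md = bl.mean_difference(frame, variable, n_boot=5000, seed=0)
    print(f"{variable}: with - without = {md.effect:+.3f} "
          f"[{md.ci_low:+.3f}, {md.ci_high:+.3f}] (paired 95% bootstrap CI)")

fit = bl.fit_quadratic(frame, n_boot=5000, seed=0)
a2, a1, a0 = fit.coefficients
print(f"score ~ {a2:+.4f}*rate^2 {a1:+.3f}*rate {a0:+.2f}: "
      "slower sessions score higher, dropping toward zero as rate leaves the band")
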