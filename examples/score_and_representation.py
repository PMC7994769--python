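"""From breathing rate to biofeedback score to tunnel vision and light.

The score is a trapezoid over the 4-12 breaths/min target band; the
representation maps it to a peripheral-vision aperture and a light level,
each with a hard floor so the trainee is never blinded, plus a pacer
waveform for guided-breathing tutorials.
"""

import breathloop as bl

band = bl.TargetBand()          # 4-12 breaths/min, zeros at 1 and 24
rep = bl.RepresentationParams()  # floor 0.25, min light 0.3

for rate in (6.0, 12.0, 18.0, 24.0, 30.0):
    score = bl.compute_score(rate, band)
    print(f"rate {rate:4.1f} breaths/min -> score {score:.2f} "
          f"-> aperture {bl.score_to_aperture(score, rep):.2f}, "
          f"light {bl.score_to_light(score, rep):.2f}")
print("note: even at score 0 the aperture stays at the floor "
      f"({rep.floor:.2f} of the full field) — the trainee can still function")

print("\nvisual pacer at 6 breaths/min (10 s cycle, inhale 40%):")
for t in (0.0, 2.0, 4.0, 7.0, 10.0):
    print(f"  t = {t:4.1f} s -> position {bl.pacer_position(t, 6.0):.2f}")
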