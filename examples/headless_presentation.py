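"""Emit per-frame stimulus states for a moving stimulus, headlessly.

A 10 s imprinting event is expanded at the 120 Hz reference refresh into
1200 ideal frame states: a translatory stimulus oscillating sinusoidally
(amplitude 150 px, period 4 s) around screen centre. The frame log is what
an on-screen player would render; here we just summarize it.
"""

import numpy as np

from imprintkit import MotionParams, PresentationEvent, frames_for_event

event = PresentationEvent(
    day=1, session=1, phase="imprinting", start_s=0.0, end_s=10.0,
    left_stimulus="red_hen", right_stimulus="dark", imprint_side="left",
)
params = MotionParams(
    mode="translatory", amplitude_px=150.0, period_s=4.0, center_x_px=960.0
)

frames = frames_for_event(event, params, refresh_hz=120.0)
xs = np.array([f.x_px for f in frames])

print(f"frames emitted: {len(frames)} (10 s x 120 Hz)")
print(f"x range: [{xs.min():.1f}, {xs.max():.1f}] px "
      f"(centre 960 +/- amplitude 150)")
print(f"mean x over whole periods: {xs[:1200 // 5 * 4 * 1].mean():.2f} px")
print(f"first frame: t={frames[0].t_s:.4f}s x={frames[0].x_px:.1f} "
      f"side={frames[0].side} visible={frames[0].visible}")
print(f"last frame:  t={frames[-1].t_s:.4f}s (half-open sampling: < 10 s)")

flicker = MotionParams(mode="flicker", on_s=2.0, off_s=1.0, center_x_px=960.0)
fl = frames_for_event(event, flicker, refresh_hz=120.0)
duty = np.mean([f.visible for f in fl])
print(f"\nflicker 2 s on / 1 s off over 10 s: duty {duty:.3f} "
      "(on/(on+off) = 0.667 over whole cycles)")
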