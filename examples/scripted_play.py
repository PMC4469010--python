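"""One scripted game: stroke, refine, guess, and read back the log.

Plays a level-1 game headlessly: a few brush strokes over the hidden
256x256 phantom, dose-free refinement, then a guess at the number of
gray circles based on blobs near the 0.5 tone in the estimate.  The
whole run is serialized in the tracking grammar and parsed back.
"""

import numpy as np

from ctbrush import parse, serialize
from ctbrush.session import Session, count_gray_blobs, session_seed

sess = Session(level=1, seed=session_seed(42, 0), n_rays=12)
H, W = sess.dims.shape
print(f"level 1: hidden image {H}x{W}, brush = 12 views x width 1")

for r in range(16, H, 32):  # eight horizontal sweeps
    added = sess.stroke([(r, 0), (r, W - 1)])
    print(f"  sweep row {r:>3}: +{added:>5} unique rays "
          f"(dose {sess.dose:>6,})")
for _ in range(3):
    sess.refine_action()

report = sess.dose_report()
print(f"dose {report.unique_rays:,} rays = {report.percent_of_T:.2f}% of "
      f"T({report.n_rays} views) = {report.T:,}")

guess = count_gray_blobs(sess.estimate)
outcome, nxt = sess.guess(guess)
print(f"guessed {guess} gray circle(s): {outcome} -> level {nxt}")

log = serialize(sess.events)
assert parse(log) == sess.events
print(f"tracking log: {len(log.splitlines())} lines, "
      f"round-trips losslessly; first lines:")
for line in log.splitlines()[:4]:
    print("   ", line)
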