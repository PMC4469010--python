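"""Closed-form dose accounting for equally spaced star views.

Prints, for a 256x256 image and the standard view counts, the total
number of unique rays T emitted when a star is brushed through every
pixel, the emitted dose E of a conventional equally spaced parallel
scan, and what fraction of each a frugal manual game (2,126 unique
rays) would have spent.  Lower percentages mean the brush found its
answer with a small fraction of a full scan's dose.
"""

from ctbrush import emitted_dose_E, spaced_angles, unique_total_T

N = 256
MANUAL = 2126  # unique rays spent in one careful interactive game

print(f"{'R':>4} {'spacing':>8} {'T':>12} {'E':>8} "
      f"{'manual/T %':>11} {'manual/E %':>11}")
for R in (5, 6, 9, 18, 36, 72, 180):
    T = unique_total_T(R, N, has_zero_ray=True)
    E = emitted_dose_E(spaced_angles(R), N, rounding="ceil")
    print(f"{R:>4} {180 / R:>7.1f}° {T:>12,} {E:>8,} "
          f"{100 * MANUAL / T:>11.3f} {100 * MANUAL / E:>11.1f}")

print("\nT = R*N^2 - N*(N-1): every pixel's star at R views, counting "
      "each geometric ray once\n(the 0-degree view collapses each row's "
      "N anchors onto one ray).\nE sums the per-view parallel-ray count "
      "N*(|cos t|+|sin t|), ceiled per view.")
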