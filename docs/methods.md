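# Methods

## Geometry and rasterization

A view angle is measured in degrees, clockwise from horizontal, with
rows indexing downward and 0-based pixel-center coordinates; views live
in [0°, 180°) because a line and its 180° opposite are the same line.
A ray is rasterized as an unweighted ("binary") staircase: stepping one
pixel at a time along the dominant axis, the off-axis coordinate is
`floor(intercept + slope*step + 0.5)` — midpoint rounding with the
half-integer tie broken upward.  The trace is computed from the line's
canonical `(axis, slope, intercept)` parameters rather than from the
anchor, so two rays with equal line identity have bit-identical pixel
chains.  Direction components smaller than 1e-12 are snapped to zero so
that the 0° and 90° views are exactly axis-aligned in floating point
(without the snap, `cos(90°) ≈ 6e-17` would make vertical lines
anchor-dependent and would push `N*(|cos|+|sin|)` just above `N`,
breaking its per-view ceiling).

**Ray identity.**  Dose is counted per *geometric line*: canonical key
= (dominant axis, slope, intercept rounded to 1e-9).  The rounding
absorbs last-ulp noise in `r0 - s*c0` for integer anchors; genuinely
distinct parallel lines through integer anchors on practical grid
sizes are separated by far more than 1e-9 in intercept.  This identity
is what makes the closed forms exact: at irrational-tangent angles no
two integer anchors share a line, so stars at all `N^2` pixels emit
`N^2` distinct rays per view, while the 0° view collapses each row's
`N` anchors onto one line — hence `T = R*N^2 - N*(N-1)`.  Staircase
truncation can map two distinct lines onto the same pixel chain on
coarse grids; those still count as two rays for dose, but contribute a
single raysum constraint (the solver deduplicates identical staircases
internally).  The staircase identity is exposed as `Ray.pixel_key` for
callers who want set semantics.

A caveat the closed forms ignore: tangents are also degenerate at 90°
(vertical lines collapse by column) and rational at 45°/135° (diagonal
collapse), so for view sets containing those angles the *measured*
unique-ray count is slightly below `T`; `count_unique_rays` and the
full-view solver report the measured count, `unique_total_T` the
closed form.  For the tabulated per-view dose `E`, per-view ceiling is
the default rounding; it is kept as a parameter because no single
simple rounding is canonical for every view count.

**Star brush.**  `R ∈ [1, 180]` views spaced `180/R` degrees apart
(one per degree at the 180 maximum), all through the central point.
Width `w` bundles `w` parallel rays per view at integer perpendicular
offsets — symmetric about zero for odd `w`, `-w/2+1 .. w/2` for even
`w` — each offset anchor rounded to the nearest pixel and dropped if it
leaves the grid.  Brush rotation is carried through the telemetry
format but the play layer always emits rotation 0.

## Reconstruction

MART with `A_0 = 1` everywhere.  Each newly selected ray is measured
against the hidden image once, registered under its canonical key, and
applied immediately; re-selecting a registered ray is a no-op (its
projection value is static, so reprojection cannot improve the image —
and costs no dose).  Refinement passes reapply all registered rays in
insertion order.  Numerical choices:

- update: `pixel * target / current_sum`, applied only to on-ray
  pixels; a zero target assigns exact zeros (conserved forever);
- a zero current sum with a positive target is skipped and counted
  (impossible on consistent systems started from ones, since a
  positive-target ray always keeps a positive hidden pixel);
- relative residual `|S_i - S| / max(S, 1e-12)`, convergence when the
  max over registered rays drops below `tol` (default 1e-6, default
  pass cap 200 — chosen for interactive-scale registries, where a few
  dozen rays converge to machine precision in tens of passes).

The full-view emulation (star at every pixel, i.e. conventional
equally spaced-view MART) assembles all distinct staircases per view
vectorially and runs the same multiplicative sweep as a compiled
(numba) kernel over a CSR layout; sweep order is view-major rather
than pixel-raster order, which changes nothing once refined since the
system is consistent.  On these dense systems the max-residual decays
roughly like 1/passes (many nearly parallel constraints), so the
package's full-view studies use `tol = 1e-5` with a 100-pass cap and a
128×128 (or smaller) phantom — enough to make the error-versus-views
trend and tone recovery unambiguous in a couple of CPU minutes.

## Level generator

Canvas: each dimension independently `256 + 128*k`, `k` uniform on
`{0, ..., level//5}`.  Shape count: `mindim//64 + random(mindim//11 -
mindim//64)` with floor division and `random(k)` uniform on `[0, k)`
(Java-style semantics; the printed rule does not state inclusivity).
Inversion: never below level 8; always when the level ends in digit 8
(this rule wins when both could apply); otherwise past level 8 with
probability 1/6.  Shapes draw kind (circle/triangle), tone
(half/full), position uniform over the canvas, and size uniform on
`[mindim/32, mindim/8]` — the size range is this package's reading of
"proportional to the canvas"; triangles are right isosceles with legs
along +x/+y from the recorded corner.  Tones are 0.0 / 0.5 / 1.0
(background / gray / full), swapped ends when inverted.  Overlaps are
allowed and painted in draw order; the answer counts *all* gray
circles drawn, and a guard redraws any shape list whose gray circles
are fully occluded (or absent) so the answer stays well defined and
at least 1.  Draw order is fixed (height, width, inversion, then per
shape: kind, tone, x, y, size), making a level a pure function of
(level, seed).

What the generator emulates: blob-like targets of known tone hidden in
clutter, the setting in which counting tumors is a meaningful task.
What it does not emulate: textured anatomy, noise in the measurements
(raysums here are exact pseudoprojections from a digitized image),
partial-volume effects, or detector physics — so passing tests show
the acquisition/reconstruction machinery is right, not that the
approach meets clinical imaging conditions.

## Sessions, strategies, telemetry

A session hides its phantom; play sees only the estimate.  Strokes are
explicit sample lists; consecutive samples are joined by dominant-axis
linear interpolation (headless stand-in for the ~60 Hz mouse sampling
that motivated interpolation in the first place), and every
interpolated central point both fires a star and is logged as a Move —
logging the post-interpolation trajectory is what makes a log replay
bit-for-bit.  Ray-count/width adjustments clamp to [1, 180] and
[1, 9] (the width cap is this package's choice; no maximum is printed
anywhere), cost nothing and log nothing; the next Move carries the new
values.  A wrong guess demotes exactly one level (floor 1), a correct
one advances one.  Per-session RNG streams are derived from
(master seed, session index), so a recorded multi-level run replays
against regenerated phantoms; replay verifies the regenerated shape
specs against the logged ones before applying moves.

The telemetry grammar is line-oriented: `==========` before each
`level(n:width:height)`, shape specs indented exactly four spaces,
`m(x,y:w^R_rot)`, `r()`, `g(n)`; booleans as `true`/`false`, LF
output, CRLF tolerated on input, file (or any text stream) as the
sink — a live socket transport is out of scope.  Serialization is
byte-deterministic and `parse ∘ serialize` is the identity on valid
event lists.

Scripted "players" (grid sweep, random walk) guess by counting
4-connected blobs within 0.15 of the 0.5 tone and at least 9 pixels —
deliberately crude: they exercise the harness and report dose ratios,
they are not a claim about human performance.

## Known limitations

- Parallel-beam stars only; no fan/cone masks, no limited-angle ranges,
  no anti-aliased or weighted rays, no SART/SIRT variants.
- The per-view-ceiling `E` matches direct evaluation only at some view
  counts (5 and 9 on a 256 grid); the rounding convention behind other
  tabulated values is not recoverable, so `E`'s rounding stays a
  parameter rather than a claim.
- Full-view convergence is capped, not exact; reported residuals make
  the stopping point explicit.
- The blob-counting player conflates gray triangles with gray circles
  and splits merged blobs poorly; strategy quality is out of scope.
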