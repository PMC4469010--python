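"""Ray and star geometry for the CT brush.

A "star" is a bundle of parallel-beam views all passing through one
central point.  Each view is rasterized as a binary (non-anti-aliased)
staircase line spanning the grid edge to edge, one pixel per step of the
dominant axis, via midpoint rounding.

Dose in this engine is counted per *unique ray*.  Two rays are the same
ray when they are the same geometric line — same direction and same
offset — regardless of which anchor they were drawn through or in which
direction they were traversed.  At irrational-tangent view angles no two
integer anchors share a line, which is what makes the closed-form totals
``T = R*N**2 - N*(N-1)`` (a 0-degree view present) and ``T = R*N**2``
(all tangents irrational) exact.  Staircase rasterization can map two
distinct lines onto the same pixel set; those still count as two rays,
matching the closed-form accounting.  The pixel-set identity is exposed
separately as :attr:`Ray.pixel_key` for callers that need to collapse
identical raysum constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

Pixel = tuple[int, int]

#: components of the direction vector smaller than this are snapped to 0
#: so that the 90-degree view is exactly vertical in floating point.
_AXIS_SNAP = 1e-12

#: decimals kept when classing line intercepts; absorbs last-ulp noise in
#: ``r0 - s*c0`` while keeping genuinely distinct parallel lines apart on
#: any grid of practical size.
_INTERCEPT_DECIMALS = 9


class DomainError(ValueError):
    """An argument lies outside the operation's domain."""


@dataclass(frozen=True)
class GridDims:
    """Height and width of a pixel grid, in pixels."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise DomainError(f"grid dimensions must be >= 1, got {self}")

    def contains(self, pixel: Sequence[int]) -> bool:
        r, c = pixel
        return 0 <= r < self.height and 0 <= c < self.width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class StarConfig:
    """Brush shape: number of views and parallel-ray width per view.

    ``n_rays`` is the number of views R, equally spaced over [0, 180);
    the program allows at most 180 (one per degree).  ``width`` bundles
    w parallel rays per view at integer perpendicular offsets; emitted
    rays per star placement is ``n_rays * width`` before deduplication.
    ``rotation`` offsets every view angle; it is recorded in tracking
    logs but the session layer always plays with rotation 0.
    """

    n_rays: int = 8
    width: int = 1
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_rays <= 180:
            raise DomainError(f"n_rays must be in [1, 180], got {self.n_rays}")
        if self.width < 1:
            raise DomainError(f"width must be >= 1, got {self.width}")

    @property
    def angles(self) -> tuple[float, ...]:
        step = 180.0 / self.n_rays
        return tuple((self.rotation + k * step) % 180.0 for k in range(self.n_rays))

    @property
    def offsets(self) -> tuple[int, ...]:
        # symmetric for odd widths; even widths take -w/2+1 .. w/2
        w = self.width
        lo = -(w - 1) // 2 if w % 2 else -w // 2 + 1
        return tuple(range(lo, lo + w))


def direction(angle: float) -> tuple[float, float]:
    """Unit direction (dcol, drow) of a view at ``angle`` degrees.

    Angles are measured clockwise from horizontal with rows indexing
    downward, so 45 degrees runs down-right.  Components below the axis
    snap tolerance are zeroed, making 0 and 90 degree views exactly
    axis-aligned.
    """
    th = math.radians(angle)
    dx, dy = math.cos(th), math.sin(th)
    if abs(dx) < _AXIS_SNAP:
        dx = 0.0
    if abs(dy) < _AXIS_SNAP:
        dy = 0.0
    return dx, dy


def line_params(anchor_rc: Sequence[float], angle: float) -> tuple[str, float, float]:
    """Canonical (axis, slope, intercept) of the line through ``anchor_rc``.

    For views within 45 degrees of horizontal the dominant axis is the
    column axis and the line is row = intercept + slope*col; otherwise
    the roles are swapped.  The (axis, slope, intercept) triple is a
    complete line identity for angles in [0, 180).
    """
    r0, c0 = float(anchor_rc[0]), float(anchor_rc[1])
    dx, dy = direction(angle)
    if abs(dx) >= abs(dy):
        s = dy / dx
        return ("col", s, r0 - s * c0)
    s = dx / dy
    return ("row", s, c0 - s * r0)


class Ray:
    """One staircase ray: an ordered edge-to-edge pixel chain plus its
    canonical line identity.

    ``rows``/``cols`` are parallel integer arrays ordered along the
    dominant axis; ``key`` is the geometric-line identity used for dose
    deduplication; ``pixel_key`` is the staircase pixel-set identity.
    """

    __slots__ = ("angle", "anchor", "rows", "cols", "key", "_pixel_key")

    def __init__(self, angle: float, anchor: Pixel,
                 rows: np.ndarray, cols: np.ndarray,
                 key: tuple) -> None:
        self.angle = angle
        self.anchor = anchor
        self.rows = rows
        self.cols = cols
        self.key = key
        self._pixel_key: frozenset | None = None

    @property
    def pixels(self) -> tuple[Pixel, ...]:
        return tuple(zip(self.rows.tolist(), self.cols.tolist()))

    @property
    def pixel_key(self) -> frozenset:
        if self._pixel_key is None:
            self._pixel_key = frozenset(zip(self.rows.tolist(), self.cols.tolist()))
        return self._pixel_key

    def __len__(self) -> int:
        return int(self.rows.size)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Ray(angle={self.angle:.3f}, anchor={self.anchor}, "
                f"n_pixels={len(self)})")


def _line_key(axis: str, s: float, b: float) -> tuple:
    return (axis, s, round(b, _INTERCEPT_DECIMALS))


def _trace(axis: str, s: float, b: float, dims: GridDims):
    """Midpoint staircase of the line (axis, slope, intercept) on the grid."""
    H, W = dims.height, dims.width
    if axis == "col":
        cols = np.arange(W, dtype=np.int64)
        rows = np.floor(b + s * cols + 0.5).astype(np.int64)
        keep = (rows >= 0) & (rows < H)
    else:
        rows = np.arange(H, dtype=np.int64)
        cols = np.floor(b + s * rows + 0.5).astype(np.int64)
        keep = (cols >= 0) & (cols < W)
    return rows[keep], cols[keep]


def rasterize_ray(anchor: Pixel, angle: float, dims: GridDims) -> Ray:
    """Full edge-to-edge staircase line through ``anchor`` at ``angle``.

    One pixel per step along the dominant axis, midpoint (Bresenham
    style) rounding through pixel centers, all weights 1.  Deterministic.
    """
    if not dims.contains(anchor):
        raise DomainError(f"anchor {anchor} outside grid {dims}")
    if not 0.0 <= angle % 360.0 or angle != angle:
        raise DomainError(f"bad angle {angle}")
    axis, s, b = line_params(anchor, angle % 180.0)
    rows, cols = _trace(axis, s, b, dims)
    return Ray(angle % 180.0, (int(anchor[0]), int(anchor[1])),
               rows, cols, _line_key(axis, s, b))


def canonical_key(ray: Ray) -> tuple:
    """Canonical identity of a ray: its geometric line.

    Equal lines get equal keys no matter the anchor chosen along the
    line or the traversal direction; parallel lines through different
    offsets, and rays at different angles, get distinct keys.
    """
    return ray.key


def make_star(center: Pixel, cfg: StarConfig, dims: GridDims) -> list[Ray]:
    """All rays of a star brush centered on ``center``.

    ``cfg.n_rays`` views at angles ``rotation + k*(180/n_rays)``; for
    width w each view contributes w parallel rays at the integer
    perpendicular offsets of :attr:`StarConfig.offsets`, each offset
    anchor rounded to the nearest pixel.  Offsets whose rounded anchor
    falls off the grid are dropped.
    """
    if not dims.contains(center):
        raise DomainError(f"center {center} outside grid {dims}")
    r0, c0 = int(center[0]), int(center[1])
    rays: list[Ray] = []
    for angle in cfg.angles:
        dx, dy = direction(angle)
        # unit perpendicular to the view direction, in (row, col) components
        pr, pc = dx, -dy
        for off in cfg.offsets:
            ar = math.floor(r0 + off * pr + 0.5)
            ac = math.floor(c0 + off * pc + 0.5)
            if not dims.contains((ar, ac)):
                continue
            rays.append(rasterize_ray((ar, ac), angle, dims))
    return rays


def count_unique_rays(dims: GridDims, angles: Iterable[float],
                      centers: Iterable[Pixel], *,
                      identity: str = "line") -> int:
    """Number of distinct rays from placing one star view per (center, angle).

    With ``identity="line"`` (default) rays are counted as geometric
    lines — the accounting behind the closed-form totals T and the
    game's dose score.  ``identity="pixels"`` collapses rays whose
    staircase pixel sets coincide, which on coarse grids is strictly
    fewer.
    """
    if identity not in ("line", "pixels"):
        raise DomainError(f"unknown identity {identity!r}")
    keys = set()
    angles = list(angles)
    for center in centers:
        for angle in angles:
            ray = rasterize_ray(center, angle, dims)
            keys.add(ray.key if identity == "line" else ray.pixel_key)
    return len(keys)


def unique_total_T(n_views: int, N: int, has_zero_ray: bool) -> int:
    """Closed-form total of unique rays with stars at every pixel of an
    N-by-N grid.

    ``R*N**2 - N*(N-1)`` when the star includes the 0-degree view (its
    rational tangent collapses each row's N anchors onto one line),
    otherwise ``R*N**2``.  Exact integer arithmetic.
    """
    if n_views < 1 or N < 1:
        raise DomainError("n_views and N must be >= 1")
    total = n_views * N * N
    if has_zero_ray:
        total -= N * (N - 1)
    return total


def n_theta(angle: float, N: int) -> float:
    """Number of equally spaced unit-width parallel rays crossing an
    N-by-N square at ``angle`` degrees.

    Evaluated as ``N*(|cos| + |sin|)``, the numerically stable form of
    ``N*(1 + |tan|)*|cos|``; finite at 90 degrees.
    """
    dx, dy = direction(angle)
    return N * (abs(dx) + abs(dy))


_ROUNDERS = {
    "ceil": math.ceil,
    "floor": math.floor,
    "round": lambda x: math.floor(x + 0.5),
    "exact": lambda x: x,
}


def emitted_dose_E(angles: Iterable[float], N: int, rounding: str = "ceil"):
    """Emitted dose of a full parallel-beam scan: sum of per-view ray
    counts ``n_theta``, each rounded per view.

    The default per-view ceiling is the convention under which the
    closed form agrees with direct evaluation at 5 and 9 equally spaced
    views on a 256 grid (1,618 and 2,930 rays); no single simple
    rounding reproduces every tabulated view count, so the rule stays a
    parameter.
    """
    angles = list(angles)
    if not angles:
        raise DomainError("angles must be non-empty")
    try:
        rnd = _ROUNDERS[rounding]
    except KeyError:
        raise DomainError(f"unknown rounding {rounding!r}") from None
    total = sum(rnd(n_theta(a, N)) for a in angles)
    return total


def spaced_angles(n_views: int, start: float = 0.0) -> list[float]:
    """``n_views`` equally spaced view angles over [0, 180) from ``start``."""
    if not 1 <= n_views <= 180:
        raise DomainError(f"n_views must be in [1, 180], got {n_views}")
    step = 180.0 / n_views
    return [(start + k * step) % 180.0 for k in range(n_views)]
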