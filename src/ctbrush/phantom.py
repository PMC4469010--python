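"""Procedural hidden-image ("level") generator.

Each level hides an image of full-tone and half-tone shapes — circles
and right isosceles triangles — on a uniform background; the half-tone
(gray) circles play the role of tumors and the goal of a level is to
count them.  Difficulty scales with level: the 256x256 base canvas can
randomly grow by 128 pixels per dimension for every 5 levels, the shape
count grows with the canvas, and from level 8 on some levels invert
their grayscale (white background, black full-tone objects).

Tone values are 0.0 / 0.5 / 1.0 for background / gray / full tone on a
normal level, with background and full tone swapped on an inverted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raygeom import DomainError, GridDims
from .tracklog import CircleSpec, LevelStart, TriangleSpec

HALFTONE = 0.5

#: canvas growth quantum (pixels) and base size
_BASE = 256
_STEP = 128


@dataclass(frozen=True)
class Shape:
    """One level shape.

    ``x``/``y`` are the column/row of the circle center or of the
    triangle's right-angle corner; ``size`` is the circle radius or the
    triangle leg length (legs run along +x and +y).  ``halftone`` marks
    the gray tumor tone.  Shapes may be clipped by the canvas.
    """

    kind: str  # "circle" | "triangle"
    x: int
    y: int
    size: int
    halftone: bool

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "triangle"):
            raise DomainError(f"unknown shape kind {self.kind!r}")
        if self.size <= 0:
            raise DomainError(f"shape size must be > 0, got {self.size}")


@dataclass(frozen=True)
class Phantom:
    level: int
    dims: GridDims
    shapes: tuple[Shape, ...]
    inverted: bool
    image: np.ndarray
    answer: int  # number of half-tone circles


def canvas_dims(level: int, rng: np.random.Generator) -> GridDims:
    """Random canvas size for a level: each dimension independently
    256 + 128*k with k uniform on {0, ..., level // 5}."""
    if level < 1:
        raise DomainError(f"level must be >= 1, got {level}")
    kmax = level // 5
    h = _BASE + _STEP * int(rng.integers(0, kmax + 1))
    w = _BASE + _STEP * int(rng.integers(0, kmax + 1))
    return GridDims(h, w)


def num_shapes(mindim: int, rng: np.random.Generator) -> int:
    """Shape count for a canvas whose minimum dimension is ``mindim``:
    ``mindim/64 + random(mindim/11 - mindim/64)`` with floor division
    and ``random(k)`` uniform on [0, k)."""
    if mindim < 64:
        raise DomainError(f"mindim must be >= 64, got {mindim}")
    base = mindim // 64
    spread = mindim // 11 - base
    extra = int(rng.integers(0, spread)) if spread > 0 else 0
    return base + extra


def is_inverted(level: int, rng: np.random.Generator) -> bool:
    """Grayscale inversion rule: never below level 8; always when the
    level ends in the digit 8; otherwise past level 8 a 1/6 chance."""
    if level < 1:
        raise DomainError(f"level must be >= 1, got {level}")
    if level < 8:
        return False
    if level % 10 == 8:
        return True
    return bool(rng.random() < 1.0 / 6.0)


def paint(dims: GridDims, shapes: tuple[Shape, ...], inverted: bool):
    """Rasterize shapes in draw order; returns (image, topmost-label map)."""
    bg, full = (1.0, 0.0) if inverted else (0.0, 1.0)
    H, W = dims.shape
    image = np.full((H, W), bg, dtype=float)
    label = np.full((H, W), -1, dtype=np.int32)
    rr, cc = np.mgrid[0:H, 0:W]
    for i, sh in enumerate(shapes):
        if sh.kind == "circle":
            mask = (cc - sh.x) ** 2 + (rr - sh.y) ** 2 <= sh.size ** 2
        else:
            mask = ((cc >= sh.x) & (rr >= sh.y)
                    & ((cc - sh.x) + (rr - sh.y) <= sh.size))
        image[mask] = HALFTONE if sh.halftone else full
        label[mask] = i
    return image, label


def make_phantom(dims: GridDims, shapes, inverted: bool,
                 level: int = 0) -> Phantom:
    """Assemble a phantom from an explicit shape list (painter's order)."""
    shapes = tuple(shapes)
    image, _ = paint(dims, shapes, inverted)
    answer = sum(1 for s in shapes if s.kind == "circle" and s.halftone)
    return Phantom(level, dims, shapes, inverted, image, answer)


def _draw_shapes(dims: GridDims, rng: np.random.Generator) -> tuple[Shape, ...]:
    H, W = dims.shape
    mindim = min(H, W)
    n = num_shapes(mindim, rng)
    lo, hi = mindim // 32, mindim // 8  # size proportional to the canvas
    shapes = []
    for _ in range(n):
        kind = "circle" if rng.integers(0, 2) == 0 else "triangle"
        halftone = bool(rng.integers(0, 2))
        x = int(rng.integers(0, W))
        y = int(rng.integers(0, H))
        size = int(rng.integers(lo, hi + 1))
        shapes.append(Shape(kind, x, y, size, halftone))
    return tuple(shapes)


def _gray_circles_visible(shapes, label) -> bool:
    present = np.unique(label)
    for i, sh in enumerate(shapes):
        if sh.kind == "circle" and sh.halftone and i not in present:
            return False
    return True


def generate_level(level: int, rng: np.random.Generator | int | None = None,
                   max_attempts: int = 200) -> Phantom:
    """Generate the hidden image for one level.

    Draw order (fixed, so a level is reproducible from its seed):
    canvas height, canvas width, inversion, then per shape its kind,
    tone, x, y, size.  Shape lists with no gray circle, or with a gray
    circle fully occluded by later shapes, are redrawn so that the
    level's answer is well defined and at least 1.
    """
    rng = np.random.default_rng(rng)
    dims = canvas_dims(level, rng)
    inverted = is_inverted(level, rng)
    for _ in range(max_attempts):
        shapes = _draw_shapes(dims, rng)
        if not any(s.kind == "circle" and s.halftone for s in shapes):
            continue
        image, label = paint(dims, shapes, inverted)
        if not _gray_circles_visible(shapes, label):
            continue
        answer = sum(1 for s in shapes if s.kind == "circle" and s.halftone)
        return Phantom(level, dims, shapes, inverted, image, answer)
    raise RuntimeError(f"could not draw a valid level in {max_attempts} tries")


def random_phantom(dims: GridDims, rng: np.random.Generator | int | None = None,
                   inverted: bool = False, level: int = 0,
                   max_attempts: int = 200) -> Phantom:
    """A phantom with the level generator's shape rules on an explicit
    canvas size (useful for scaled-down studies); same redraw guards as
    :func:`generate_level`."""
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        shapes = _draw_shapes(dims, rng)
        if not any(s.kind == "circle" and s.halftone for s in shapes):
            continue
        image, label = paint(dims, shapes, inverted)
        if not _gray_circles_visible(shapes, label):
            continue
        answer = sum(1 for s in shapes if s.kind == "circle" and s.halftone)
        return Phantom(level, dims, shapes, inverted, image, answer)
    raise RuntimeError(f"could not draw a valid phantom in {max_attempts} tries")


def shape_events(phantom: Phantom) -> list:
    """Tracklog events describing a phantom: its level header followed
    by one shape spec per shape, in draw order."""
    events: list = [LevelStart(phantom.level, phantom.dims.width,
                               phantom.dims.height)]
    for sh in phantom.shapes:
        if sh.kind == "triangle":
            events.append(TriangleSpec(sh.x, sh.y, sh.size, sh.halftone))
        else:
            events.append(CircleSpec(sh.x, sh.y, sh.size, sh.halftone))
    return events


def shapes_from_events(events) -> tuple[Shape, ...]:
    """Inverse of the shape part of :func:`shape_events`."""
    shapes = []
    for ev in events:
        if isinstance(ev, TriangleSpec):
            shapes.append(Shape("triangle", ev.x, ev.y, ev.size, ev.halftone))
        elif isinstance(ev, CircleSpec):
            shapes.append(Shape("circle", ev.x, ev.y, ev.radius, ev.halftone))
    return tuple(shapes)
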