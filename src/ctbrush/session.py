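"""Headless gameplay: brush state, strokes, dose accounting, progression.

A :class:`Session` plays one level.  The phantom is held privately —
play-facing queries see only the reconstruction estimate, which is
built exclusively from raysums of rays the player has irradiated.
Strokes are explicit sample lists (there is no real mouse here);
consecutive samples are joined by linear interpolation and a star is
placed at every interpolated central point.  Dose is the number of
distinct rays ever emitted; re-stroking covered ground adds nothing.

Every irradiated central point is appended to the event log as a Move,
so replaying a log against the same seed reproduces the final dose and
estimate exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from . import mart
from .phantom import Phantom, generate_level, shape_events
from .raygeom import (DomainError, GridDims, Pixel, StarConfig, make_star,
                      spaced_angles, unique_total_T, emitted_dose_E)
from .tracklog import Guess, Move, Refine, TrackEvent

MAX_RAYS = 180
MAX_WIDTH = 9


def interpolate(p0: Pixel, p1: Pixel) -> list[Pixel]:
    """Integer points of the segment p0 -> p1, one per dominant-axis
    step, endpoints included, no repeats."""
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    n = max(abs(dr), abs(dc))
    if n == 0:
        return [(int(r0), int(c0))]
    path = []
    for i in range(n + 1):
        t = i / n
        path.append((int(np.floor(r0 + t * dr + 0.5)),
                     int(np.floor(c0 + t * dc + 0.5))))
    return path


@dataclass
class BrushState:
    """Brush cursor position and star shape, with the program's bounds
    (1..180 rays, width 1..9) enforced by clamping."""

    center: Pixel
    cfg: StarConfig

    def clamp(self) -> None:
        n = min(max(self.cfg.n_rays, 1), MAX_RAYS)
        w = min(max(self.cfg.width, 1), MAX_WIDTH)
        if (n, w) != (self.cfg.n_rays, self.cfg.width):
            self.cfg = replace(self.cfg, n_rays=n, width=w)


@dataclass(frozen=True)
class DoseReport:
    """Dose summary: unique rays spent so far, per-stroke increments,
    and the closed-form references T (all-pixel-stars total) and E
    (equally spaced full scan) for the current number of views."""

    unique_rays: int
    per_stroke: tuple[int, ...]
    n_rays: int
    width: int
    T: int | None
    E: int | None

    @property
    def percent_of_T(self) -> float | None:
        return None if not self.T else 100.0 * self.unique_rays / self.T

    @property
    def percent_of_E(self) -> float | None:
        return None if not self.E else 100.0 * self.unique_rays / self.E


class Session:
    """One level of headless play over a hidden phantom."""

    def __init__(self, level: int = 1,
                 seed: int | np.random.Generator | None = None,
                 phantom: Phantom | None = None,
                 n_rays: int = 8, width: int = 1) -> None:
        if phantom is None:
            phantom = generate_level(level, np.random.default_rng(seed))
        self._phantom = phantom
        self.level = phantom.level if phantom.level else level
        self.dims: GridDims = phantom.dims
        self.recon = mart.ReconState.initial(self.dims)
        self.brush = BrushState(center=(self.dims.height // 2,
                                        self.dims.width // 2),
                                cfg=StarConfig(n_rays=n_rays, width=width))
        self.brush.clamp()
        self.events: list[TrackEvent] = list(shape_events(phantom))
        self._stroke_doses: list[int] = []
        self.finished = False

    # -- play-facing queries -------------------------------------------------

    @property
    def dose(self) -> int:
        return self.recon.dose

    @property
    def estimate(self) -> np.ndarray:
        """Copy of the current reconstruction (never the hidden image)."""
        return np.array(self.recon.estimate, copy=True)

    # -- actions -------------------------------------------------------------

    def stroke(self, samples: Sequence[Pixel]) -> int:
        """Apply one mouse-down stroke through ``samples``.

        Consecutive samples are linearly interpolated; at every point of
        the resulting path a star is placed and each not-yet-selected
        ray is measured and processed.  Returns the dose added (number
        of newly unique rays).
        """
        if not samples:
            raise DomainError("stroke needs at least one sample")
        for p in samples:
            if not self.dims.contains(p):
                raise DomainError(f"sample {p} outside grid {self.dims}")
        path: list[Pixel] = [tuple(map(int, samples[0]))]
        for a, b in zip(samples, samples[1:]):
            path.extend(interpolate(a, b)[1:])
        added = 0
        cfg = self.brush.cfg
        for pt in path:
            for ray in make_star(pt, cfg, self.dims):
                _, new = mart.process_new_ray(self.recon, ray,
                                              self._phantom.image)
                added += int(new)
            self.events.append(Move(x=pt[1], y=pt[0], width=cfg.width,
                                    n_rays=cfg.n_rays, rotation=0))
        self.brush.center = path[-1]
        self._stroke_doses.append(added)
        return added

    def adjust_rays(self, delta: int) -> int:
        """Change the number of views by ``delta`` (clamped to 1..180);
        costs nothing and records no event."""
        self.brush.cfg = replace(self.brush.cfg, n_rays=min(
            max(self.brush.cfg.n_rays + delta, 1), MAX_RAYS))
        return self.brush.cfg.n_rays

    def adjust_width(self, delta: int) -> int:
        """Change the brush width by ``delta`` (clamped to 1..9)."""
        self.brush.cfg = replace(self.brush.cfg, width=min(
            max(self.brush.cfg.width + delta, 1), MAX_WIDTH))
        return self.brush.cfg.width

    def refine_action(self) -> None:
        """One dose-free refinement pass over all selected rays."""
        mart.refine(self.recon)
        self.events.append(Refine())

    def guess(self, count: int) -> tuple[str, int]:
        """Submit the gray-circle count; returns (outcome, next_level).

        A correct guess advances one level; a wrong one demotes one
        level (never below 1).  The next level is played on a fresh
        session.
        """
        if count < 0:
            raise DomainError("guess must be >= 0")
        self.events.append(Guess(count))
        self.finished = True
        if count == self._phantom.answer:
            return "advance", self.level + 1
        return "demote", max(1, self.level - 1)

    def dose_report(self) -> DoseReport:
        cfg = self.brush.cfg
        H, W = self.dims.shape
        T = E = None
        if H == W:
            T = unique_total_T(cfg.n_rays, H, has_zero_ray=True)
            E = emitted_dose_E(spaced_angles(cfg.n_rays), H)
        return DoseReport(self.dose, tuple(self._stroke_doses),
                          cfg.n_rays, cfg.width, T, E)


# ---------------------------------------------------------------------------
# scripted strategies

#: a strategy maps the session to the next action:
#:   ("stroke", samples) | ("adjust_rays", d) | ("adjust_width", d)
#:   | ("refine",) | ("guess", n) | ("stop",)
Strategy = Callable[[Session], tuple]


def count_gray_blobs(estimate: np.ndarray, tol: float = 0.15,
                     min_size: int = 9) -> int:
    """4-connected components of near-half-tone pixels, ignoring specks.

    The crude "player" used by scripted strategies: it counts connected
    regions whose value sits within ``tol`` of the 0.5 tumor tone.  It
    cannot tell gray circles from gray triangles, so it is a fallible
    player by design.
    """
    mask = np.abs(estimate - 0.5) < tol
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    blobs = 0
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            size = 0
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                size += 1
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] \
                            and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            if size >= min_size:
                blobs += 1
    return blobs


def grid_sweep_strategy(row_step: int = 1, refines: int = 3) -> Strategy:
    """Sweep the brush across every ``row_step``-th row, refine, guess."""
    state = {"row": 0, "refines": 0}

    def step(session: Session) -> tuple:
        H, W = session.dims.shape
        if state["row"] < H:
            r = state["row"]
            state["row"] += row_step
            return ("stroke", [(r, 0), (r, W - 1)])
        if state["refines"] < refines:
            state["refines"] += 1
            return ("refine",)
        return ("guess", count_gray_blobs(session.estimate))

    return step


def random_walk_strategy(rng: np.random.Generator, n_strokes: int = 12,
                         stroke_len: int = 6, refines: int = 3) -> Strategy:
    """Random short strokes, then refine and guess."""
    state = {"strokes": 0, "refines": 0}

    def step(session: Session) -> tuple:
        H, W = session.dims.shape
        if state["strokes"] < n_strokes:
            state["strokes"] += 1
            samples = [(int(rng.integers(0, H)), int(rng.integers(0, W)))
                       for _ in range(stroke_len)]
            return ("stroke", samples)
        if state["refines"] < refines:
            state["refines"] += 1
            return ("refine",)
        return ("guess", count_gray_blobs(session.estimate))

    return step


def run_strategy(session: Session, strategy: Strategy,
                 max_steps: int = 10_000) -> tuple[str, int]:
    """Drive a session with a strategy until it guesses (or stops)."""
    for _ in range(max_steps):
        action = strategy(session)
        name = action[0]
        if name == "stroke":
            session.stroke(action[1])
        elif name == "adjust_rays":
            session.adjust_rays(action[1])
        elif name == "adjust_width":
            session.adjust_width(action[1])
        elif name == "refine":
            session.refine_action()
        elif name == "guess":
            return session.guess(action[1])
        elif name == "stop":
            return "stop", session.level
        else:
            raise DomainError(f"unknown action {name!r}")
    return "stop", session.level


# ---------------------------------------------------------------------------
# replay

def session_seed(master_seed: int, index: int) -> np.random.Generator:
    """RNG for the ``index``-th session of a play run.

    Level generation and play randomness are split into per-session
    streams derived from one master seed, so a recorded run replays
    identically level by level.
    """
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


def replay(events: Sequence[TrackEvent], master_seed: int) -> list[Session]:
    """Re-execute a tracking log against regenerated phantoms.

    Each level segment regenerates its phantom from the master seed and
    the segment's position in the log; the logged shape specs must match
    the regenerated ones (otherwise the log does not belong to this
    seed).  Moves, refines and the guess are then replayed verbatim.
    Returns the finished sessions, one per level segment.
    """
    from .tracklog import (CircleSpec, Guess, LevelStart, Move, Refine,
                           TriangleSpec)

    sessions: list[Session] = []
    current: Session | None = None
    shape_i = 0
    for ev in events:
        if isinstance(ev, LevelStart):
            rng = session_seed(master_seed, len(sessions))
            ph = generate_level(ev.level, rng)
            if (ph.dims.width, ph.dims.height) != (ev.width, ev.height):
                raise TrackLogMismatch(
                    f"level {ev.level}: logged canvas {ev.width}x{ev.height} "
                    f"!= regenerated {ph.dims.width}x{ph.dims.height}")
            current = Session(phantom=ph)
            sessions.append(current)
            shape_i = 0
        elif isinstance(ev, (TriangleSpec, CircleSpec)):
            if current is None:
                raise TrackLogMismatch("shape spec before any level")
            if shape_i >= len(current._phantom.shapes):
                raise TrackLogMismatch("more shape specs than shapes")
            # the session's own events already carry the regenerated
            # specs; verify the log agrees
            if current.events[1 + shape_i] != ev:
                raise TrackLogMismatch(
                    f"shape spec #{shape_i} mismatch: log {ev} != "
                    f"regenerated {current.events[1 + shape_i]}")
            shape_i += 1
        elif isinstance(ev, Move):
            if current is None:
                raise TrackLogMismatch("move before any level")
            current.brush.cfg = StarConfig(n_rays=ev.n_rays, width=ev.width,
                                           rotation=float(ev.rotation))
            current.stroke([(ev.y, ev.x)])
        elif isinstance(ev, Refine):
            if current is None:
                raise TrackLogMismatch("refine before any level")
            current.refine_action()
        elif isinstance(ev, Guess):
            if current is None:
                raise TrackLogMismatch("guess before any level")
            current.guess(ev.count)
    return sessions


class TrackLogMismatch(ValueError):
    """A tracking log is inconsistent with the seed it is replayed under."""
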