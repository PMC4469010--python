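"""Writer and parser for the pseudo-function tracking grammar.

A tracking log is a line-oriented byte stream of "pseudo-functions",
one per line.  Each level opens with a line of ten equal signs followed
by ``level(number:width:height)``; the triangles and circles describing
the level follow, each indented by exactly four spaces; brush moves,
refinements and the final guess follow unindented:

    ==========
    level(3:256:384)
        t(40,51,12:false)
        c(120,45,12:true)
    m(100,120:3^8_0)
    r()
    g(2)

``m(x,y:w^n_r)`` carries, left to right, the brush x and y coordinates,
brush width, number of rays, and rotation (recorded, but always 0 from
the session layer).  Booleans are spelled ``true``/``false``.  Output
uses LF newlines; the parser also accepts CRLF and a missing final
newline.  The canonical sink is a file, but any text stream works (the
original piped the same bytes over TCP).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

SEPARATOR = "=" * 10
INDENT = " " * 4


class TrackLogError(ValueError):
    """Structural or syntax error in a tracking log."""

    def __init__(self, message: str, line: int | None = None,
                 col: int | None = None) -> None:
        self.line = line
        self.col = col
        where = f" (line {line}, col {col})" if line is not None else ""
        super().__init__(message + where)


@dataclass(frozen=True)
class LevelStart:
    level: int
    width: int
    height: int


@dataclass(frozen=True)
class TriangleSpec:
    x: int
    y: int
    size: int
    halftone: bool


@dataclass(frozen=True)
class CircleSpec:
    x: int
    y: int
    radius: int
    halftone: bool


@dataclass(frozen=True)
class Move:
    x: int
    y: int
    width: int
    n_rays: int
    rotation: int


@dataclass(frozen=True)
class Refine:
    pass


@dataclass(frozen=True)
class Guess:
    count: int


TrackEvent = Union[LevelStart, TriangleSpec, CircleSpec, Move, Refine, Guess]


def _bool(value: bool) -> str:
    return "true" if value else "false"


def serialize(events: Iterable[TrackEvent]) -> str:
    """Serialize events to the log text (byte-deterministic, LF newlines)."""
    lines: list[str] = []
    in_level = False
    for i, ev in enumerate(events):
        if isinstance(ev, LevelStart):
            lines.append(SEPARATOR)
            lines.append(f"level({ev.level}:{ev.width}:{ev.height})")
            in_level = True
        elif isinstance(ev, TriangleSpec):
            if not in_level:
                raise TrackLogError(
                    f"shape event #{i} outside any level")
            lines.append(f"{INDENT}t({ev.x},{ev.y},{ev.size}:{_bool(ev.halftone)})")
        elif isinstance(ev, CircleSpec):
            if not in_level:
                raise TrackLogError(
                    f"shape event #{i} outside any level")
            lines.append(f"{INDENT}c({ev.x},{ev.y},{ev.radius}:{_bool(ev.halftone)})")
        elif isinstance(ev, Move):
            lines.append(f"m({ev.x},{ev.y}:{ev.width}^{ev.n_rays}_{ev.rotation})")
        elif isinstance(ev, Refine):
            lines.append("r()")
        elif isinstance(ev, Guess):
            lines.append(f"g({ev.count})")
        else:
            raise TrackLogError(f"unknown event type {type(ev).__name__}")
    return "".join(line + "\n" for line in lines)


_LEVEL_RE = re.compile(r"level\((\d+):(\d+):(\d+)\)$")
_SHAPE_RE = re.compile(r"([tc])\((\d+),(\d+),(\d+):(true|false)\)$")
_MOVE_RE = re.compile(r"m\((\d+),(\d+):(\d+)\^(\d+)_(\d+)\)$")
_GUESS_RE = re.compile(r"g\((\d+)\)$")


def parse(text: str) -> list[TrackEvent]:
    """Parse log text back into events (inverse of :func:`serialize`).

    Tolerates CRLF line endings, trailing whitespace and a missing
    final newline; anything else malformed raises :class:`TrackLogError`
    with the offending line and column.
    """
    events: list[TrackEvent] = []
    expect_level = False
    in_level = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if expect_level:
            m = _LEVEL_RE.match(line)
            if m is None:
                raise TrackLogError(
                    "expected level(...) after separator", lineno, 1)
            events.append(LevelStart(int(m[1]), int(m[2]), int(m[3])))
            expect_level = False
            in_level = True
            continue
        if line == SEPARATOR:
            expect_level = True
            continue
        if not line:
            continue
        if line.startswith(" "):
            body = line.lstrip(" ")
            indent = len(line) - len(body)
            if indent != 4:
                raise TrackLogError(
                    f"shape lines take exactly 4 leading spaces, got {indent}",
                    lineno, 1)
            if not in_level:
                raise TrackLogError("shape line outside any level", lineno, 1)
            m = _SHAPE_RE.match(body)
            if m is None:
                raise TrackLogError(f"malformed shape line {body!r}", lineno, 5)
            x, y, size = int(m[2]), int(m[3]), int(m[4])
            halftone = m[5] == "true"
            events.append(TriangleSpec(x, y, size, halftone) if m[1] == "t"
                          else CircleSpec(x, y, size, halftone))
            continue
        if line.startswith("level("):
            raise TrackLogError(
                "level(...) must be preceded by a separator line", lineno, 1)
        if line == "r()":
            events.append(Refine())
            continue
        m = _MOVE_RE.match(line)
        if m is not None:
            events.append(Move(int(m[1]), int(m[2]), int(m[3]),
                               int(m[4]), int(m[5])))
            continue
        m = _GUESS_RE.match(line)
        if m is not None:
            events.append(Guess(int(m[1])))
            continue
        raise TrackLogError(f"unrecognized line {line!r}", lineno, 1)
    if expect_level:
        raise TrackLogError("log ends after a separator with no level line")
    return events


def write_tracklog(path, events: Iterable[TrackEvent]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(serialize(events))


def read_tracklog(path) -> list[TrackEvent]:
    with open(path, "r", newline="") as fh:
        return parse(fh.read())
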