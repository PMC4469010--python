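"""Grayscale image I/O: PGM (P2/P5) and PNG, values scaled to [0, 1]."""

from __future__ import annotations

import numpy as np
from PIL import Image


def read_gray(path) -> np.ndarray:
    """Read a grayscale image as floats in [0, 1]."""
    with Image.open(path) as img:
        if img.mode not in ("L", "I", "I;16", "F"):
            img = img.convert("L")
        arr = np.asarray(img, dtype=float)
    peak = arr.max()
    if peak > 1.0:
        # scale by the sample format's full range
        full = 65535.0 if peak > 255 else 255.0
        arr = arr / full
    return arr


def _to_uint8(values: np.ndarray) -> np.ndarray:
    arr = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    return np.floor(arr * 255.0 + 0.5).astype(np.uint8)


def write_pgm(path, values: np.ndarray) -> None:
    """Write [0, 1] values as a plain-text (P2) PGM with maxval 255."""
    arr = _to_uint8(values)
    h, w = arr.shape
    with open(path, "w", newline="\n") as fh:
        fh.write(f"P2\n{w} {h}\n255\n")
        for row in arr:
            fh.write(" ".join(str(v) for v in row.tolist()) + "\n")


def write_png(path, values: np.ndarray) -> None:
    """Write [0, 1] values as an 8-bit grayscale PNG."""
    Image.fromarray(_to_uint8(values), mode="L").save(path)


def write_gray(path, values: np.ndarray) -> None:
    """Write by extension: .pgm -> P2 text, anything else via Pillow."""
    p = str(path)
    if p.lower().endswith(".pgm"):
        write_pgm(p, values)
    else:
        write_png(p, values)
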