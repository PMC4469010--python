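"""Raysum measurement and the MART reconstruction core.

The engine reconstructs a hidden attenuation image from raysums along
individually selected staircase rays.  Updates are multiplicative
(MART): each processed ray rescales the pixels it crosses so that the
estimate's raysum matches the measured one.  The estimate starts as a
uniform image of ones — a multiplicative scheme can never resurrect a
zero, so zeros in the start image are forbidden and a measured raysum
of zero permanently zeroes every pixel on its ray.

Two execution paths share the same update rule: an object-level path
(:class:`ReconState`, :func:`process_new_ray`, :func:`refine`) used by
interactive sessions, and a compiled CSR path used by
:func:`full_view_reconstruction` to emulate conventional equally
spaced-view MART by sweeping stars through every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .raygeom import (DomainError, GridDims, Ray, StarConfig, direction,
                      make_star, spaced_angles)

EPS = _kernels.EPS

ImageGrid = np.ndarray


def raysum(image: ImageGrid, ray: Ray) -> float:
    """Unweighted sum of image values over the ray's pixels."""
    if len(ray) == 0:
        raise DomainError("ray has no pixels")
    H, W = image.shape
    if ray.rows.max() >= H or ray.cols.max() >= W:
        raise DomainError("ray pixels fall outside the image")
    return float(image[ray.rows, ray.cols].sum())


def _update_inplace(est: ImageGrid, ray: Ray, target: float) -> str:
    vals = est[ray.rows, ray.cols]
    if target == 0.0:
        est[ray.rows, ray.cols] = 0.0
        return "zeroed"
    s = float(vals.sum())
    if s <= 0.0:
        return "skipped"
    est[ray.rows, ray.cols] = vals * target / s
    return "updated"


def mart_update(estimate: ImageGrid, ray: Ray, target: float) -> ImageGrid:
    """Multiplicative update of one ray toward its target raysum.

    Every pixel on the ray is multiplied by ``target / current_raysum``;
    off-ray pixels are untouched, so afterwards the ray's raysum equals
    the target to floating tolerance.  A zero target zeroes the ray.  If
    the current raysum is zero while the target is positive the update
    is skipped (nothing to rescale); callers needing to detect this use
    the state-level API, which counts skips.
    """
    if target < 0:
        raise DomainError(f"negative target raysum {target}")
    out = np.array(estimate, dtype=float, copy=True)
    _update_inplace(out, ray, float(target))
    return out


class RayRegistry:
    """Insertion-ordered map from canonical ray key to (ray, raysum).

    Its size is the emitted dose: each unique ray is measured (and
    counted) exactly once.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple, tuple[Ray, float]] = {}

    def __contains__(self, key: tuple) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def add(self, ray: Ray, measured: float) -> None:
        if measured < 0:
            raise DomainError(f"negative raysum {measured}")
        if ray.key in self._entries:
            raise DomainError(f"duplicate ray key {ray.key}")
        self._entries[ray.key] = (ray, measured)

    def items(self):
        """(ray, raysum) pairs in insertion order."""
        return self._entries.values()


@dataclass
class ReconState:
    """Current estimate plus the registry of already-measured rays."""

    estimate: ImageGrid
    registry: RayRegistry = field(default_factory=RayRegistry)
    refine_count: int = 0
    skipped: int = 0

    @classmethod
    def initial(cls, dims: GridDims) -> "ReconState":
        return cls(estimate=np.ones(dims.shape, dtype=float))

    @property
    def dose(self) -> int:
        return len(self.registry)


def process_new_ray(state: ReconState, ray: Ray,
                    hidden: ImageGrid) -> tuple[ReconState, bool]:
    """Measure and apply one ray, unless it was already selected.

    A ray whose canonical key is already registered adds no dose and
    changes nothing (reprojecting a static projection cannot improve the
    image).  A new ray has its hidden raysum measured once, registered,
    and one MART update applied.
    """
    if hidden.shape != state.estimate.shape:
        raise DomainError(
            f"hidden image {hidden.shape} does not match estimate "
            f"{state.estimate.shape}")
    if ray.key in state.registry:
        return state, False
    measured = raysum(hidden, ray)
    state.registry.add(ray, measured)
    if _update_inplace(state.estimate, ray, measured) == "skipped":
        state.skipped += 1
    return state, True


def refine(state: ReconState) -> ReconState:
    """One dose-free pass of MART updates over all registered rays.

    Rays are revisited in insertion order against their stored raysums;
    the registry (hence the dose) is unchanged.
    """
    for ray, measured in state.registry.items():
        if _update_inplace(state.estimate, ray, measured) == "skipped":
            state.skipped += 1
    state.refine_count += 1
    return state


def residual(state: ReconState) -> float:
    """Max over registered rays of |S_i - S| / max(S, eps)."""
    worst = 0.0
    for ray, measured in state.registry.items():
        s = float(state.estimate[ray.rows, ray.cols].sum())
        worst = max(worst, abs(s - measured) / max(measured, EPS))
    return worst


@dataclass(frozen=True)
class ConvergenceInfo:
    converged: bool
    passes: int
    residual: float

    @property
    def reason(self) -> str:
        return "tolerance" if self.converged else "max_passes"


def refine_to_convergence(state: ReconState, tol: float = 1e-6,
                          max_passes: int = 200) -> ConvergenceInfo:
    """Refine until the max relative raysum residual drops below ``tol``
    or ``max_passes`` refinement passes have run."""
    if tol <= 0:
        raise DomainError(f"tol must be > 0, got {tol}")
    passes = 0
    res = residual(state)
    while res >= tol and passes < max_passes:
        refine(state)
        passes += 1
        res = residual(state)
    return ConvergenceInfo(res < tol, passes, res)


# ---------------------------------------------------------------------------
# full-view emulation (stars through every pixel, compiled sweeps)

def _angle_system(angle: float, H: int, W: int):
    """All distinct rays at one view angle with anchors at every pixel.

    Returns (flat_indices, counts, n_lines): the staircase pixel runs of
    every *distinct staircase* at this angle, and the number of distinct
    geometric lines (the dose actually attributed to the angle).  Lines
    whose staircases coincide contribute one constraint but still count
    individually toward dose.
    """
    dx, dy = direction(angle)
    r0 = np.arange(H, dtype=float)
    c0 = np.arange(W, dtype=float)
    if abs(dx) >= abs(dy):
        s = dy / dx
        b = np.unique(np.round((r0[:, None] - s * c0[None, :]).ravel(), 9))
        span = np.arange(W, dtype=np.int64)
        other = np.floor(b[:, None] + s * span[None, :] + 0.5).astype(np.int64)
        valid = (other >= 0) & (other < H)
        enc = np.where(valid, other, -1)
        uniq = np.unique(enc, axis=0)
        keep = uniq >= 0
        flats = (uniq * W + span[None, :])[keep]
    else:
        s = dx / dy
        b = np.unique(np.round((c0[None, :] - s * r0[:, None]).ravel(), 9))
        span = np.arange(H, dtype=np.int64)
        other = np.floor(b[:, None] + s * span[None, :] + 0.5).astype(np.int64)
        valid = (other >= 0) & (other < W)
        enc = np.where(valid, other, -1)
        uniq = np.unique(enc, axis=0)
        keep = uniq >= 0
        flats = (span[None, :] * W + uniq)[keep]
    counts = keep.sum(axis=1)
    nonempty = counts > 0
    return flats, counts[nonempty], int(b.size)


def _build_system(angles, H: int, W: int):
    all_flats, all_counts = [], []
    n_lines = 0
    for angle in angles:
        flats, counts, lines = _angle_system(angle, H, W)
        all_flats.append(flats)
        all_counts.append(counts)
        n_lines += lines
    indices = np.concatenate(all_flats).astype(np.int64)
    counts = np.concatenate(all_counts)
    indptr = np.zeros(counts.size + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indices, indptr, n_lines


@dataclass(frozen=True)
class FullViewResult:
    image: ImageGrid
    residuals: tuple[float, ...]  # after the initial pass and each refine
    n_unique_rays: int            # dose, counted as geometric lines
    n_constraints: int            # distinct staircases actually iterated
    converged: bool
    skipped: int

    @property
    def passes(self) -> int:
        return len(self.residuals)


def full_view_report(hidden: ImageGrid, n_views: int, tol: float = 1e-6,
                     max_passes: int = 200) -> FullViewResult:
    """Emulated conventional MART: stars at every pixel, refined to
    convergence, with per-pass residuals.

    ``n_views`` equally spaced views over [0, 180) starting at 0
    degrees.  Every pixel's star is processed with registry-style
    deduplication, then dose-free refinement passes run until the max
    relative residual falls below ``tol`` or ``max_passes`` refinement
    passes have been spent.
    """
    if not 1 <= n_views <= 180:
        raise DomainError(f"n_views must be in [1, 180], got {n_views}")
    hidden = np.asarray(hidden, dtype=float)
    if hidden.ndim != 2:
        raise DomainError("hidden image must be 2-D")
    if (hidden < 0).any():
        raise DomainError("hidden image must be non-negative")
    H, W = hidden.shape
    indices, indptr, n_lines = _build_system(spaced_angles(n_views), H, W)
    targets = np.add.reduceat(hidden.ravel()[indices], indptr[:-1])
    targets[np.diff(indptr) == 0] = 0.0
    est = np.ones(H * W, dtype=float)
    residuals: list[float] = []
    skipped_total = 0
    converged = False
    for _ in range(max_passes + 1):  # first pass is the processing pass
        skipped, _ = _kernels.mart_sweep(est, indices, indptr, targets)
        skipped_total += int(skipped)
        res = float(_kernels.max_residual(est, indices, indptr, targets))
        residuals.append(res)
        if res < tol:
            converged = True
            break
    return FullViewResult(est.reshape(H, W), tuple(residuals), n_lines,
                          int(targets.size), converged, skipped_total)


def full_view_reconstruction(hidden: ImageGrid, n_views: int,
                             tol: float = 1e-6,
                             max_passes: int = 200) -> ImageGrid:
    """Reconstructed image of :func:`full_view_report`."""
    return full_view_report(hidden, n_views, tol, max_passes).image


def line_profile(image: ImageGrid, row: int) -> np.ndarray:
    """Horizontal line profile: the row of pixel values at ``row``."""
    if not 0 <= row < image.shape[0]:
        raise DomainError(f"row {row} outside image of height {image.shape[0]}")
    return np.array(image[row], dtype=float, copy=True)


def relative_error(recon: ImageGrid, reference: ImageGrid) -> float:
    """Relative L2 error ||recon - reference|| / ||reference||."""
    ref = np.asarray(reference, dtype=float)
    denom = float(np.linalg.norm(ref))
    return float(np.linalg.norm(np.asarray(recon, dtype=float) - ref)) / max(denom, EPS)
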