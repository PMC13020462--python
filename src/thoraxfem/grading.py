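"""Graded 1-D point distributions for structured meshing.

All meshes in this package are tensor-product grids; local refinement (e.g.
around electrode patches) is realized by grading the 1-D gridline spacing
along each axis.  The generator below walks the axis with a spacing field
``h(x)`` that equals ``h_fine`` inside refinement bands and relaxes linearly
back to ``h_coarse`` outside them, then rescales so the last point lands
exactly on the end of the interval.  The construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RefineBand", "graded_points"]

# growth rate of spacing with distance from a refinement band; 0.3 keeps
# neighbouring-cell size ratios below ~1.3 for typical h_coarse/h_fine
_GROWTH = 0.3


@dataclass(frozen=True)
class RefineBand:
    """Interval [lo, hi] to be resolved with spacing ``h_fine``."""

    lo: float
    hi: float
    h_fine: float

    def spacing_at(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return self.h_fine
        d = self.lo - x if x < self.lo else x - self.hi
        return self.h_fine + _GROWTH * d


def graded_points(
    start: float,
    stop: float,
    h_coarse: float,
    bands: tuple[RefineBand, ...] = (),
    snap: tuple[float, ...] = (),
) -> np.ndarray:
    """Monotone point distribution on [start, stop].

    Spacing is ``min(h_coarse, min_b band.spacing_at(x))``.  Points listed in
    ``snap`` (interior axis positions such as region-boundary planes) are
    inserted exactly, with the walk restarted at each of them so gridlines
    conform to those planes.
    """
    if stop <= start:
        raise ValueError("graded_points: stop must exceed start")
    if h_coarse <= 0:
        raise ValueError("graded_points: h_coarse must be positive")
    anchors = [start]
    for p in sorted(p for p in snap if start < p < stop):
        if p - anchors[-1] > 1e-9:
            anchors.append(p)
    if stop - anchors[-1] <= 1e-9:
        anchors.pop()
    anchors.append(stop)
    pts: list[float] = [start]
    for a, b in zip(anchors[:-1], anchors[1:]):
        seg = _walk_segment(a, b, h_coarse, bands)
        pts.extend(seg[1:])
    return np.asarray(pts)


def _spacing(x: float, h_coarse: float, bands: tuple[RefineBand, ...]) -> float:
    h = h_coarse
    for b in bands:
        h = min(h, b.spacing_at(x))
    return h


def _walk_segment(
    a: float, b: float, h_coarse: float, bands: tuple[RefineBand, ...]
) -> np.ndarray:
    pts = [a]
    x = a
    while x < b - 1e-12:
        x = x + _spacing(x, h_coarse, bands)
        pts.append(min(x, b))
    arr = np.asarray(pts)
    if len(arr) < 2:
        return np.array([a, b])
    # rescale the walked offsets so the segment ends exactly at b while
    # preserving the relative spacing profile
    last = arr[-1]
    if last != b or arr[-1] - arr[-2] < 0.45 * _spacing(b, h_coarse, bands):
        # drop an over-short final interval before rescaling
        if len(arr) > 2 and arr[-1] - arr[-2] < 0.45 * _spacing(b, h_coarse, bands):
            arr = np.delete(arr, -2)
    arr = a + (arr - a) * (b - a) / (arr[-1] - a)
    return arr
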