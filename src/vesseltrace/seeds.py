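"""Automatic seed-point detection by sparse-grid boundary search.

A sparse grid of horizontal and vertical scan lines samples the image; the
1-D edge kernel [1, 2, 0, -2, -1] flags candidate boundary points where a
line crosses a vessel wall.  Opposite-polarity candidate pairs whose image
gradients are anti-parallel and of comparable magnitude yield seed points at
the pair midpoint, with half-width = separation/2 and initial direction
perpendicular to the local gradient.  A 5x5 neighborhood check against the
center-line map suppresses seeds on already-traced vessels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .vesselness import HessianField

__all__ = [
    "EDGE_KERNEL",
    "SeedParams",
    "GridLine",
    "BoundaryCandidate",
    "SeedPoint",
    "build_grid",
    "boundary_candidates",
    "pair_and_validate",
    "initial_direction",
    "detect_seeds",
]

log = logging.getLogger(__name__)

#: discrete approximation of the first-derivative-of-Gaussian edge filter
EDGE_KERNEL = np.array([1.0, 2.0, 0.0, -2.0, -1.0])


@dataclass(frozen=True)
class SeedParams:
    """Tunables of seed detection.

    The validation tolerances (anti-parallel angle, magnitude ratio, pair
    separation) are engineering choices, exposed here for adjustment.
    """

    grid_spacing: int = 10          # px between scan lines
    noise_floor_factor: float = 4.0  # x median |response| of the line
    antiparallel_tol_deg: float = 30.0
    magnitude_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    separation_bounds: tuple[float, float] = (2.0, 40.0)
    gradient_sigma: float = 1.0


@dataclass(frozen=True)
class GridLine:
    axis: str        # "h" = constant row, "v" = constant column
    index: int       # the fixed row/column
    profile: np.ndarray

    def point_at(self, offset: float) -> np.ndarray:
        """(x, y) position of a given offset along the line."""
        if self.axis == "h":
            return np.array([float(offset), float(self.index)])
        return np.array([float(self.index), float(offset)])


@dataclass(frozen=True)
class BoundaryCandidate:
    position: np.ndarray  # (x, y)
    line_id: int
    offset: int
    response: float       # signed filter response (+ = entering dark vessel)
    gradient: np.ndarray = field(default_factory=lambda: np.zeros(2))


@dataclass(frozen=True)
class SeedPoint:
    """Validated tracing start: axis position, unit direction, half-width."""

    position: np.ndarray
    direction: np.ndarray
    half_width: float
    strength: float = 0.0  # |response| of the weaker pair member

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.direction), 1.0):
            raise ValueError("direction must be a unit vector")
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")


def _positions(n: int, spacing: int) -> list[int]:
    pos = list(range(spacing, n, spacing))
    return pos if pos else [n // 2]


def build_grid(image_or_shape, spacing: int) -> list[GridLine]:
    """Scan lines at rows/columns spacing, 2*spacing, ... inside the image.

    Accepts an image (profiles carry its intensities) or a bare (h, w) shape
    (profiles zero).  When spacing exceeds an axis extent a single center
    line is used on that axis.
    """
    if spacing < 2:
        raise ValueError("spacing must be >= 2")
    if isinstance(image_or_shape, np.ndarray) and image_or_shape.ndim == 2:
        img = np.asarray(image_or_shape, dtype=float)
        h, w = img.shape
    else:
        h, w = image_or_shape
        img = None
    lines: list[GridLine] = []
    for row in _positions(h, spacing):
        profile = img[row, :] if img is not None else np.zeros(w)
        lines.append(GridLine("h", row, profile))
    for col in _positions(w, spacing):
        profile = img[:, col] if img is not None else np.zeros(h)
        lines.append(GridLine("v", col, profile))
    return lines


def boundary_candidates(profile: np.ndarray, params: SeedParams | None = None,
                        line: GridLine | None = None, line_id: int = 0) -> list[BoundaryCandidate]:
    """Edge-filter extrema along one scan-line profile.

    Returns |response| local extrema above a robust noise floor, non-maximum
    suppressed within 3 px, ordered by offset.  A positive response marks a
    light-to-dark transition (entering a dark vessel).
    """
    params = params or SeedParams()
    profile = np.asarray(profile, dtype=float)
    if profile.size < len(EDGE_KERNEL):
        return []
    resp = ndi.correlate1d(profile, EDGE_KERNEL, mode="nearest")
    mag = np.abs(resp)
    floor = max(params.noise_floor_factor * float(np.median(mag)), 1e-9)
    # local extrema of |response|
    idx = [
        i for i in range(1, len(mag) - 1)
        if mag[i] >= floor and mag[i] >= mag[i - 1] and mag[i] > mag[i + 1]
    ]
    # non-maximum suppression within a 3-px neighborhood
    keep: list[int] = []
    for i in sorted(idx, key=lambda j: -mag[j]):
        if all(abs(i - j) > 3 for j in keep):
            keep.append(i)
    out = []
    for i in sorted(keep):
        pos = line.point_at(i) if line is not None else np.array([float(i), 0.0])
        out.append(BoundaryCandidate(position=pos, line_id=line_id, offset=i, response=float(resp[i])))
    return out


def initial_direction(gradient) -> np.ndarray:
    """Unit vector perpendicular to a gradient; +x half-plane convention.

    Of the two perpendiculars the one with positive x-component is returned
    (positive y on ties); the tracer runs both ways so the sign is purely a
    convention.
    """
    g = np.asarray(gradient, dtype=float)
    n = np.linalg.norm(g)
    if n == 0:
        raise ValueError("zero gradient has no direction")
    d = np.array([-g[1], g[0]]) / n
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return d


def _map_neighborhood_clear(labels: np.ndarray, point: np.ndarray, half: int = 2) -> bool:
    """True when the (2*half+1)^2 neighborhood of *point* is unlabeled."""
    h, w = labels.shape
    x, y = int(round(point[0])), int(round(point[1]))
    if not (0 <= x < w and 0 <= y < h):
        return False
    y0, y1 = max(0, y - half), min(h, y + half + 1)
    x0, x1 = max(0, x - half), min(w, x + half + 1)
    return bool(np.all(labels[y0:y1, x0:x1] == 0))


def pair_and_validate(candidates: list[BoundaryCandidate], field: HessianField,
                      labels: np.ndarray | None = None,
                      params: SeedParams | None = None) -> list[SeedPoint]:
    """Pair consecutive opposite-polarity candidates of one line into seeds.

    A pair is accepted when the line enters (response > 0) then leaves
    (response < 0) a dark vessel, the two image gradients are anti-parallel
    within tolerance and of comparable magnitude, the separation is within
    the plausible vessel-width range, and the midpoint's 5x5 neighborhood of
    the center-line map is untraced.
    """
    params = params or SeedParams()
    if labels is None:
        labels = np.zeros(field.shape, dtype=np.int32)
    cands = sorted(candidates, key=lambda c: c.offset)
    seeds: list[SeedPoint] = []
    lo, hi = params.separation_bounds
    cos_tol = np.cos(np.radians(params.antiparallel_tol_deg))
    for a, b in zip(cands[:-1], cands[1:]):
        if not (a.response > 0 > b.response):
            continue  # need entering-then-leaving polarity
        sep = float(np.linalg.norm(b.position - a.position))
        if not (lo <= sep <= hi):
            log.debug("seed pair rejected: separation %.1f px", sep)
            continue
        g = field.gradient_many(np.stack([a.position, b.position]), params.gradient_sigma)
        na, nb = np.linalg.norm(g[0]), np.linalg.norm(g[1])
        if na == 0 or nb == 0:
            continue
        if float(g[0] @ g[1]) / (na * nb) > -cos_tol:
            log.debug("seed pair rejected: gradients not anti-parallel")
            continue
        ratio = na / nb
        if not (params.magnitude_ratio_bounds[0] <= ratio <= params.magnitude_ratio_bounds[1]):
            log.debug("seed pair rejected: magnitude ratio %.2f", ratio)
            continue
        mid = 0.5 * (a.position + b.position)
        if not _map_neighborhood_clear(labels, mid):
            log.debug("seed pair rejected: midpoint near a traced segment")
            continue
        seeds.append(SeedPoint(
            position=mid,
            direction=initial_direction(g[0]),
            half_width=sep / 2.0,
            strength=min(abs(a.response), abs(b.response)),
        ))
    return seeds


def detect_seeds(image_or_field, labels: np.ndarray | None = None,
                 params: SeedParams | None = None) -> list[SeedPoint]:
    """Full sparse-grid seed detection on an image.

    Seeds are returned strongest-first (descending weaker-member filter
    response) so high-contrast vessels are traced first.
    """
    params = params or SeedParams()
    field = image_or_field if isinstance(image_or_field, HessianField) else HessianField(image_or_field)
    lines = build_grid(field.image, params.grid_spacing)
    seeds: list[SeedPoint] = []
    for line_id, line in enumerate(lines):
        cands = boundary_candidates(line.profile, params, line=line, line_id=line_id)
        seeds.extend(pair_and_validate(cands, field, labels, params))
    seeds.sort(key=lambda s: -s.strength)
    return seeds
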