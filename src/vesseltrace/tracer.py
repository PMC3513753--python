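"""Exploratory center-line tracing with semicircular vesselness profiles.

From each validated seed the tracer alternately *estimates* the next
center-line point (maximum of the vesselness sampled on a semicircular
look-ahead profile, filtered by direction-field parallelism and uniformity),
*refines* it by recentering between the two vessel edges found on
perpendicular gradient profiles, and *advances* by an adaptive step:

    look-ahead  r^k   = round(rho * max(R^k, R^{k+1}))      (>= 5 px floor)
    step size   a^k   = max(1, (1 - omega^k/pi) * R^k)

where omega^k is the angular change of the tracing direction.  Tracing runs
bidirectionally from the seed and stops when the profile leaves the image,
no valid vessel point survives the checks, a previously traced segment is
met (the traces are joined), or the percent dynamic range of the vesselness
across the vessel drops to the background level.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field as dc_field

import numpy as np

from .seeds import SeedParams, SeedPoint, detect_seeds
from .vesselness import HessianField, VesselnessParams, scales_from_halfwidth

__all__ = [
    "TracerConfig",
    "TracePoint",
    "ScanProfile",
    "CenterlineSegment",
    "CenterlineMap",
    "StopDecision",
    "scan_semicircle",
    "select_next_point",
    "SelectDecision",
    "detect_edges",
    "recenter",
    "update_direction",
    "adapt_lookahead",
    "adapt_step",
    "dynamic_range",
    "should_stop",
    "rasterize_connection",
    "trace_from_seed",
    "trace_tree",
]

log = logging.getLogger(__name__)

MIN_HALFWIDTH = 0.75  # px; recentering never shrinks the state below this


@dataclass(frozen=True)
class TracerConfig:
    """Tracer tunables; defaults are the tuned operating point."""

    rho: float = 1.3                 # look-ahead factor (> 1)
    tau: float = 0.0                 # dynamic-range stop threshold (%)
    min_segment_length: int = 20     # px; shorter traces are discarded
    parallel_tol: float = np.radians(25.0)
    uniformity_tol: float = np.radians(30.0)
    v_floor: float = 0.05            # vesselness floor for profile maxima
    edge_floor: float = 1.0          # minimum edge contrast (intensity/px)
    max_steps: int = 2000            # per direction, safety bound
    max_halfwidth: float = 20.0      # px; sanity clamp on edge-based updates

    def __post_init__(self) -> None:
        if not self.rho > 1:
            raise ValueError("rho must exceed 1")
        if self.min_segment_length < 0:
            raise ValueError("min_segment_length must be >= 0")


@dataclass(frozen=True)
class TracePoint:
    """One center-line sample: position p, unit direction u, half-width R."""

    position: np.ndarray
    direction: np.ndarray
    half_width: float


@dataclass(frozen=True)
class ScanProfile:
    """Semicircular look-ahead profile around a trace point."""

    angles: np.ndarray        # theta in [-pi/2, pi/2], strictly increasing
    points: np.ndarray        # (N, 2) sample coordinates
    values: np.ndarray        # vesselness at each sample
    orientations: np.ndarray  # phi_opt at each sample (radians mod pi)
    radius: float
    out_of_field: bool = False


@dataclass
class CenterlineSegment:
    points: list[TracePoint]
    segment_number: int
    bifurcations: list[int] = dc_field(default_factory=list)
    termination_forward: str = "max_steps"
    termination_backward: str = "max_steps"
    pixels: np.ndarray | None = None  # rasterized (M, 2) int chain

    @property
    def termination_reason(self) -> str:
        return self.termination_forward


@dataclass
class CenterlineMap:
    """Integer label image of traced pixels, one label per accepted segment."""

    labels: np.ndarray
    next_segment_number: int = 1

    @classmethod
    def blank(cls, shape) -> "CenterlineMap":
        return cls(labels=np.zeros(shape, dtype=np.int32))


@dataclass(frozen=True)
class SelectDecision:
    chosen: np.ndarray | None
    branch_seeds: list[tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class StopDecision:
    action: str                 # "continue" | "stop" | "join"
    reason: str | None = None
    join_pixel: np.ndarray | None = None


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def _angdiff_mod_pi(a, b):
    """Smallest angle between two orientations (mod pi), in [0, pi/2]."""
    d = np.mod(a - b, np.pi)
    return np.minimum(d, np.pi - d)


def scan_semicircle(field: HessianField, p, u, r: float,
                    params: VesselnessParams, scales) -> ScanProfile:
    """Sample vesselness on a semicircle of radius r ahead of p along u.

    Samples at ~1-px arc spacing (count = round(pi*r) + 1) spanning theta in
    [-pi/2, +pi/2] about the tracing direction.  If any sample leaves the
    image the profile is returned flagged out_of_field with empty values.
    """
    if r < 1:
        raise ValueError("look-ahead radius must be >= 1")
    p = np.asarray(p, dtype=float)
    base = np.arctan2(u[1], u[0])
    n = int(round(np.pi * r)) + 1
    theta = np.linspace(-np.pi / 2, np.pi / 2, n)
    ang = base + theta
    pts = p[None, :] + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if not np.all(field.inside(pts)):
        return ScanProfile(theta, pts, np.array([]), np.array([]), float(r), out_of_field=True)
    v, _, phi = field.multiscale_many(pts, scales, params)
    return ScanProfile(theta, pts, v, phi, float(r))


def select_next_point(profile: ScanProfile, p, u, cfg: TracerConfig) -> SelectDecision:
    """Choose the next center-line point among profile maxima.

    A local maximum q survives when (a) the chord direction p->q is parallel
    (mod pi) to the local vessel orientation phi(q) within parallel_tol, and
    (b) the orientations of the two profile neighbors on each side of q agree
    with phi(q) within uniformity_tol.  The survivor closest in angle to the
    tracing direction u is chosen; the rest become branch seeds.
    """
    p = np.asarray(p, dtype=float)
    v = profile.values
    if v.size == 0:
        return SelectDecision(None, [])
    n = len(v)
    maxima = [
        i for i in range(n)
        if v[i] > cfg.v_floor
        and (i == 0 or v[i] >= v[i - 1])
        and (i == n - 1 or v[i] > v[i + 1])
    ]
    u_ang = np.arctan2(u[1], u[0])
    survivors: list[tuple[float, int]] = []
    for i in maxima:
        q = profile.points[i]
        chord = np.arctan2(q[1] - p[1], q[0] - p[0])
        if _angdiff_mod_pi(chord, profile.orientations[i]) > cfg.parallel_tol:
            continue
        nbrs = [j for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < n]
        if any(_angdiff_mod_pi(profile.orientations[j], profile.orientations[i]) > cfg.uniformity_tol
               for j in nbrs):
            continue
        dev = abs(np.mod(chord - u_ang + np.pi, 2 * np.pi) - np.pi)
        survivors.append((dev, i))
    if not survivors:
        return SelectDecision(None, [])
    survivors.sort()
    _, best = survivors[0]
    branches = []
    for _, i in survivors[1:]:
        q = profile.points[i]
        branches.append((q.copy(), _unit(q - p)))
    return SelectDecision(profile.points[best].copy(), branches)


def _cross_normal(u: np.ndarray) -> np.ndarray:
    """u rotated +90 degrees (x right, y down): the cross-vessel normal."""
    return np.array([-u[1], u[0]])


def detect_edges(field: HessianField, q0, u0, w: float, edge_floor: float = 1.0):
    """Edge offsets (eL, eR) on perpendicular gradient profiles, or None.

    Walks integer offsets 1..w from q0 along -n and +n (n = u0 rotated +90
    deg), scoring each sample by |grad_x| + |grad_y|; the maximum on each
    side, refined to sub-pixel precision by a parabolic fit through its two
    neighbors, is the edge.  None when either side has no contrast above
    edge_floor or lies fully outside the image.
    """
    if w < 2:
        raise ValueError("profile length must be >= 2")
    q0 = np.asarray(q0, dtype=float)
    n_hat = _cross_normal(np.asarray(u0, dtype=float))
    offsets = np.arange(1, int(np.floor(w)) + 1, dtype=float)
    out = []
    for sign in (-1.0, +1.0):
        pts = q0[None, :] + sign * offsets[:, None] * n_hat[None, :]
        ok = field.inside(pts)
        if not np.any(ok):
            return None
        g = field.gradient_many(pts[ok])
        contrast = np.abs(g[:, 0]) + np.abs(g[:, 1])
        if contrast.max() < edge_floor:
            return None
        i = int(np.argmax(contrast))
        e = offsets[ok][i]
        if 0 < i < len(contrast) - 1:  # parabolic sub-pixel peak refinement
            y0, y1, y2 = contrast[i - 1], contrast[i], contrast[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                e += 0.5 * (y0 - y2) / denom
        out.append(float(e))
    return out[0], out[1]  # (eL, eR)


def recenter(q0, u0, eL: float, eR: float):
    """Shift q0 to the midpoint of its detected edges.

    q1 = q0 + ((eR - eL)/2) * n;  the updated half-width is (eL + eR)/2.
    """
    if eL < 0 or eR < 0:
        raise ValueError("edge offsets must be non-negative")
    q0 = np.asarray(q0, dtype=float)
    n_hat = _cross_normal(np.asarray(u0, dtype=float))
    q1 = q0 + 0.5 * (eR - eL) * n_hat
    return q1, 0.5 * (eL + eR)


def update_direction(p, q1) -> np.ndarray:
    """Unit tracing direction from p toward the refined next point q1."""
    d = np.asarray(q1, dtype=float) - np.asarray(p, dtype=float)
    return _unit(d)


def adapt_lookahead(R_cur: float, R_next: float, rho: float) -> int:
    """Adaptive look-ahead radius r = round(rho * max(R^k, R^{k+1})).

    A constant 5-px radius is used for vessels thinner than 5 px, where
    rounding errors would otherwise collapse r onto the half-width.
    """
    if not (R_cur > 0 and R_next > 0):
        raise ValueError("half-widths must be positive")
    if not rho > 1:
        raise ValueError("rho must exceed 1")
    m = max(R_cur, R_next)
    if m < 5.0:
        return 5
    return int(round(rho * m))


def adapt_step(omega: float, R_cur: float) -> float:
    """Self-adaptive step size a = (1 - omega/pi) * R, floored at 1 px."""
    if not (0 <= omega <= np.pi):
        raise ValueError("omega must be in [0, pi]")
    if not R_cur > 0:
        raise ValueError("half-width must be positive")
    return max(1.0, (1.0 - omega / np.pi) * R_cur)


def dynamic_range(vL: np.ndarray, vR: np.ndarray, eL: float, eR: float, w: float) -> float:
    """Percent dynamic range of vesselness across the vessel.

    Signal = mean vesselness inside the edges (offsets [0, eL] left and
    [0, eR] right, offset 0 being the center); background = mean beyond the
    edges out to w.  Returns (Sg - B)/B * 100, or +inf when B = 0 (a vessel
    against an empty background never triggers the stop).
    """
    vL = np.asarray(vL, dtype=float)
    vR = np.asarray(vR, dtype=float)
    iL, iR = int(np.floor(eL)), int(np.floor(eR))
    sig = np.concatenate([vL[: iL + 1], vR[: iR + 1]])
    bgL = vL[iL + 1: int(np.floor(w)) + 1]
    bgR = vR[iR + 1: int(np.floor(w)) + 1]
    bg = np.concatenate([bgL, bgR])
    if bg.size == 0:  # edges at the profile end: fall back to outermost samples
        bg = np.concatenate([vL[-1:], vR[-1:]])
    sg = float(np.mean(sig))
    b = float(np.mean(bg))
    if b <= 0:
        return np.inf
    return (sg - b) / b * 100.0


def rasterize_connection(p, q) -> np.ndarray:
    """8-connected digital line between integer pixels p and q (inclusive).

    Bresenham contract: every step changes x or y by at most one; the chain
    length is the Chebyshev distance plus one.
    """
    x0, y0 = int(round(p[0])), int(round(p[1]))
    x1, y1 = int(round(q[0])), int(round(q[1]))
    n = max(abs(x1 - x0), abs(y1 - y0))
    if n == 0:
        return np.array([[x0, y0]])
    ts = np.arange(n + 1) / n
    xs = np.round(x0 + ts * (x1 - x0)).astype(int)
    ys = np.round(y0 + ts * (y1 - y0)).astype(int)
    return np.stack([xs, ys], axis=1)


def _map_hits(clmap: CenterlineMap, pts: np.ndarray) -> np.ndarray:
    """Subset of pts (rounded) whose map pixel is already labeled."""
    labels = clmap.labels
    h, w = labels.shape
    xi = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    yi = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    hit = labels[yi, xi] > 0
    return pts[hit]


def should_stop(profile: ScanProfile, decision: SelectDecision | None,
                gamma: float | None, chain: np.ndarray | None,
                clmap: CenterlineMap, cfg: TracerConfig, p) -> StopDecision:
    """Apply the stopping criteria in their canonical order.

    1. profile leaves the image field; 2. no valid vessel point; 3. a traced
    pixel on the profile or connecting chain (join at the pixel nearest p);
    4. percent dynamic range at or below tau.
    """
    p = np.asarray(p, dtype=float)
    if profile.out_of_field:
        return StopDecision("stop", "out_of_field")
    if decision is not None and decision.chosen is None:
        return StopDecision("stop", "no_vessel_point")
    candidates = [_map_hits(clmap, profile.points)]
    if chain is not None and len(chain):
        candidates.append(_map_hits(clmap, chain.astype(float)))
    hits = np.concatenate([c for c in candidates if len(c)]) if any(len(c) for c in candidates) else None
    if hits is not None and len(hits):
        d = np.linalg.norm(hits - p[None, :], axis=1)
        return StopDecision("join", "intersection", hits[int(np.argmin(d))])
    if gamma is not None and gamma <= cfg.tau:
        return StopDecision("stop", "dynamic_range")
    return StopDecision("continue")


def _trace_direction(field: HessianField, p0, u0, R0, clmap: CenterlineMap,
                     cfg: TracerConfig, params: VesselnessParams):
    """One-directional trace; returns (points, reason, branches, bif_idx, join_px)."""
    p = np.asarray(p0, dtype=float)
    u = _unit(np.asarray(u0, dtype=float))
    R = max(float(R0), MIN_HALFWIDTH)
    R_prev = R
    points: list[TracePoint] = [TracePoint(p.copy(), u.copy(), R)]
    branches: list[tuple[np.ndarray, np.ndarray, float]] = []
    bif_idx: list[int] = []
    reason = "max_steps"
    join_px = None
    for _ in range(cfg.max_steps):
        r = adapt_lookahead(R_prev, R, cfg.rho)
        scales = scales_from_halfwidth(R)
        profile = scan_semicircle(field, p, u, r, params, scales)
        if profile.out_of_field:
            reason = "out_of_field"
            break
        decision = select_next_point(profile, p, u, cfg)
        stop = should_stop(profile, decision, None, None, clmap, cfg, p)
        if stop.action == "join":
            join_px = stop.join_pixel
            reason = "intersection"
            break
        if stop.action == "stop":
            reason = stop.reason or "no_vessel_point"
            break
        q0 = decision.chosen
        u0dir = update_direction(p, q0)
        edges = detect_edges(field, q0, u0dir, w=r, edge_floor=cfg.edge_floor)
        if edges is None:
            reason = "dynamic_range"
            break
        eL, eR = edges
        q1, R_new = recenter(q0, u0dir, eL, eR)
        R_new = float(np.clip(R_new, MIN_HALFWIDTH, cfg.max_halfwidth))
        if not np.all(field.inside(q1[None, :])):
            reason = "out_of_field"
            break
        # vesselness along the cross profiles at q1 for the dynamic-range stop
        n_hat = _cross_normal(u0dir)
        offs = np.arange(0, int(np.floor(r)) + 1, dtype=float)
        ptsL = q1[None, :] - offs[:, None] * n_hat[None, :]
        ptsR = q1[None, :] + offs[:, None] * n_hat[None, :]
        okL, okR = field.inside(ptsL), field.inside(ptsR)
        vL, _, _ = field.multiscale_many(ptsL[okL], scales, params)
        vR, _, _ = field.multiscale_many(ptsR[okR], scales, params)
        gamma = dynamic_range(vL, vR, min(eL, okL.sum() - 1), min(eR, okR.sum() - 1), r)
        chain = rasterize_connection(p, q1)
        stop = should_stop(profile, decision, gamma, chain, clmap, cfg, p)
        if stop.action == "join":
            join_px = stop.join_pixel
            reason = "intersection"
            break
        if stop.action == "stop":
            reason = stop.reason or "dynamic_range"
            break
        u_new = update_direction(p, q1)
        omega = float(np.arccos(np.clip(u @ u_new, -1.0, 1.0)))
        alpha = adapt_step(omega, R)
        p_next = p + alpha * u_new
        if not np.all(field.inside(p_next[None, :])):
            reason = "out_of_field"
            break
        if decision.branch_seeds:
            bif_idx.append(len(points) - 1)
            for bq, bu in decision.branch_seeds:
                branches.append((bq, bu, R_new))
        points.append(TracePoint(p_next, u_new, R_new))
        R_prev, R, u, p = R, R_new, u_new, p_next
    return points, reason, branches, bif_idx, join_px


def _chain_from_points(points: list[TracePoint], join_px=None) -> np.ndarray:
    """Rasterize consecutive trace points (plus a join tail) into a pixel chain."""
    if not points:
        return np.zeros((0, 2), dtype=int)
    pieces = []
    prev = points[0].position
    pieces.append(np.array([[int(round(prev[0])), int(round(prev[1]))]]))
    for tp in points[1:]:
        seg = rasterize_connection(prev, tp.position)
        pieces.append(seg[1:])
        prev = tp.position
    if join_px is not None:
        seg = rasterize_connection(prev, join_px)
        pieces.append(seg[1:])
    chain = np.concatenate([p for p in pieces if len(p)])
    # drop consecutive duplicates introduced by sub-pixel rounding
    keep = np.ones(len(chain), dtype=bool)
    keep[1:] = np.any(chain[1:] != chain[:-1], axis=1)
    return chain[keep]


def _self_intersects(chain: np.ndarray, gap: int = 8) -> bool:
    """True when the chain revisits a pixel it left more than *gap* steps ago."""
    last_seen: dict[tuple[int, int], int] = {}
    for i, (x, y) in enumerate(map(tuple, chain)):
        j = last_seen.get((x, y))
        if j is not None and i - j > gap:
            return True
        last_seen[(x, y)] = i
    return False


def trace_from_seed(field: HessianField, seed: SeedPoint, clmap: CenterlineMap,
                    cfg: TracerConfig | None = None,
                    params: VesselnessParams | None = None):
    """Bidirectional trace from one seed.

    Returns (segment, branch_seeds) on acceptance or (None, []) when the
    trace is shorter than min_segment_length or intersects itself.  Accepted
    segments are rasterized into the map under a fresh segment number.
    """
    cfg = cfg or TracerConfig()
    params = params or VesselnessParams()
    fwd, reason_f, br_f, bif_f, join_f = _trace_direction(
        field, seed.position, seed.direction, seed.half_width, clmap, cfg, params)
    bwd, reason_b, br_b, bif_b, join_b = _trace_direction(
        field, seed.position, -seed.direction, seed.half_width, clmap, cfg, params)
    # merge: backward reversed (directions flipped to point forward) + forward
    merged: list[TracePoint] = [
        TracePoint(tp.position, -tp.direction, tp.half_width) for tp in reversed(bwd[1:])
    ] + fwd
    nb = len(bwd) - 1
    bifurcations = sorted([nb - 1 - i for i in bif_b] + [nb + i for i in bif_f])
    number = clmap.next_segment_number
    chain_fwd = _chain_from_points(fwd, join_f)
    chain_bwd = _chain_from_points(bwd, join_b)
    chain = np.concatenate([chain_bwd[::-1], chain_fwd[1:]]) if len(chain_fwd) else chain_bwd[::-1]
    if len(chain) < cfg.min_segment_length:
        log.debug("trace discarded: %d px < min length", len(chain))
        return None, []
    if _self_intersects(chain):
        log.debug("trace discarded: self-intersection")
        return None, []
    h, w = clmap.labels.shape
    xi = np.clip(chain[:, 0], 0, w - 1)
    yi = np.clip(chain[:, 1], 0, h - 1)
    free = clmap.labels[yi, xi] == 0
    clmap.labels[yi[free], xi[free]] = number
    clmap.next_segment_number += 1
    seg = CenterlineSegment(
        points=merged,
        segment_number=number,
        bifurcations=[i for i in bifurcations if 0 <= i < len(merged)],
        termination_forward=reason_f,
        termination_backward=reason_b,
        pixels=chain,
    )
    branch_seeds = [
        SeedPoint(position=q, direction=u, half_width=max(Rb, MIN_HALFWIDTH))
        for q, u, Rb in br_f + br_b
    ]
    return seg, branch_seeds


def trace_tree(image_or_field, cfg: TracerConfig | None = None,
               params: VesselnessParams | None = None,
               seed_params: SeedParams | None = None,
               seeds: list[SeedPoint] | None = None):
    """Trace the full vessel tree of an image.

    Seeds come from automatic detection unless given; the queue also receives
    bifurcation-spawned seeds.  Each seed passes the 5x5 repetition guard
    against the center-line map before tracing.  Deterministic for a fixed
    image and configuration.
    """
    cfg = cfg or TracerConfig()
    params = params or VesselnessParams()
    field = image_or_field if isinstance(image_or_field, HessianField) else HessianField(image_or_field)
    clmap = CenterlineMap.blank(field.shape)
    if seeds is None:
        seeds = detect_seeds(field, clmap.labels, seed_params)
    if not seeds:
        log.warning("no seeds found; nothing to trace")
        return [], clmap
    queue = deque(seeds)
    segments: list[CenterlineSegment] = []
    while queue:
        seed = queue.popleft()
        if not _neighborhood_clear(clmap.labels, seed.position):
            continue
        seg, branch_seeds = trace_from_seed(field, seed, clmap, cfg, params)
        if seg is not None:
            segments.append(seg)
            queue.extend(branch_seeds)
    return segments, clmap


def _neighborhood_clear(labels: np.ndarray, point, half: int = 2) -> bool:
    h, w = labels.shape
    x, y = int(round(point[0])), int(round(point[1]))
    if not (0 <= x < w and 0 <= y < h):
        return False
    return bool(np.all(labels[max(0, y - half): y + half + 1, max(0, x - half): x + half + 1] == 0))
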