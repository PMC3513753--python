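"""Synthetic vessel phantoms with analytic ground truth.

Center-lines are concatenations of constant-curvature arcs.  A constant-
curvature arc starting at position r0 with unit tangent t0 follows

    r(l) = r0 + (1/K) * phi1(l) @ t0,
    phi1(l) = [[sin(lK), 1-cos(lK)], [cos(lK)-1, sin(lK)]],

with the K -> 0 limit the straight line r0 + l*t0.  The half-width profile is
a linear taper modulated by raised-cosine stenosis bumps; the image renders
the projection of a circular lumen (intensity dip proportional to the chord
length through the vessel) on a uniform background, optionally degraded with
additive white Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ArcSpec",
    "LesionSpec",
    "VesselPhantom",
    "GroundTruth",
    "arc_centerline",
    "radius_profile",
    "render_image",
    "add_gaussian_noise",
    "build_phantom",
    "table1_phantoms",
    "generate_table1_dataset",
    "SNR_LEVELS_DB",
]

#: the four noise levels applied to every base phantom (None = noiseless)
SNR_LEVELS_DB = (None, 20.0, 16.0, 10.0)

DEFAULT_CONTRAST = 100.0
DEFAULT_BACKGROUND = 200.0


@dataclass(frozen=True)
class ArcSpec:
    """One constant-curvature center-line piece: curvature (1/px), length (px)."""

    curvature: float
    length: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("arc length must be positive")
        if abs(self.curvature) * self.length > 2 * np.pi:
            raise ValueError("arc sweeps more than a full turn")


@dataclass(frozen=True)
class LesionSpec:
    """A localized diameter stenosis.

    percent_stenosis is the diameter reduction at the apex (95 leaves 5% of
    the local baseline); extent is the full arc-length support of the bump;
    asymmetry in [0, 1] skews the rise/fall lengths (0 = symmetric).
    """

    center_arclength: float
    percent_stenosis: float
    extent: float
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.percent_stenosis <= 100):
            raise ValueError("percent_stenosis must be in [0, 100]")
        if not self.extent > 0:
            raise ValueError("extent must be positive")
        if not (0 <= self.asymmetry <= 1):
            raise ValueError("asymmetry must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic center-line sampled at 1-px arc-length spacing."""

    points: np.ndarray    # (N, 2) as (x, y)
    tangents: np.ndarray  # (N, 2) unit vectors
    radii: np.ndarray     # (N,) half-widths in px

    def __post_init__(self) -> None:
        if not (len(self.points) == len(self.tangents) == len(self.radii)):
            raise ValueError("points, tangents and radii must have equal length")


@dataclass(frozen=True)
class VesselPhantom:
    """Generative description of one synthetic vessel."""

    arcs: tuple[ArcSpec, ...]
    base_half_width: float = 5.0
    taper: float = 0.0
    lesions: tuple[LesionSpec, ...] = ()
    contrast: float = DEFAULT_CONTRAST
    background: float = DEFAULT_BACKGROUND
    snr_db: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_half_width >= 1:
            raise ValueError("base_half_width must be >= 1 px")
        if not (0 <= self.contrast <= self.background):
            raise ValueError("need 0 <= contrast <= background")

    @property
    def total_length(self) -> float:
        return sum(a.length for a in self.arcs)


def arc_centerline(r0, t0, arc: ArcSpec, ds: float = 1.0):
    """Sample one constant-curvature arc at arc lengths 0, ds, ..., L.

    Returns (points, tangents); the final row gives the exit state for
    chaining the next arc.
    """
    r0 = np.asarray(r0, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    if not np.isclose(np.linalg.norm(t0), 1.0):
        raise ValueError("t0 must be a unit vector")
    if not ds > 0:
        raise ValueError("ds must be positive")
    n = int(np.floor(arc.length / ds + 1e-9))
    ls = np.append(np.arange(n + 1) * ds, arc.length) if n * ds < arc.length - 1e-9 else np.arange(n + 1) * ds
    k = arc.curvature
    if abs(k) < 1e-12:
        pts = r0[None, :] + ls[:, None] * t0[None, :]
        tans = np.tile(t0, (len(ls), 1))
        return pts, tans
    lk = ls * k
    sin, cos = np.sin(lk), np.cos(lk)
    # r(l) = r0 + (1/K) t0 @ [ [sin, 1-cos], [cos-1, sin] ]
    dx = (sin * t0[0] + (cos - 1.0) * t0[1]) / k
    dy = ((1.0 - cos) * t0[0] + sin * t0[1]) / k
    pts = r0[None, :] + np.stack([dx, dy], axis=1)
    tans = np.stack([cos * t0[0] - sin * t0[1], sin * t0[0] + cos * t0[1]], axis=1)
    return pts, tans


def chain_centerline(arcs, r0=(0.0, 0.0), t0=(1.0, 0.0), ds: float = 1.0):
    """C1 concatenation of arcs sampled at uniform arc-length spacing ds."""
    pts_all, tan_all = [], []
    r, t = np.asarray(r0, dtype=float), np.asarray(t0, dtype=float)
    for i, arc in enumerate(arcs):
        pts, tans = arc_centerline(r, t, arc, ds)
        r, t = pts[-1], tans[-1] / np.linalg.norm(tans[-1])
        if i > 0:  # drop the duplicated joint sample
            pts, tans = pts[1:], tans[1:]
        pts_all.append(pts)
        tan_all.append(tans)
    return np.concatenate(pts_all), np.concatenate(tan_all)


def _lesion_bump(l: np.ndarray, lesion: LesionSpec) -> np.ndarray:
    """Raised-cosine bump: 1 at the apex, 0 outside the (skewed) extent."""
    half = lesion.extent / 2.0
    rise = max(half * (1.0 - lesion.asymmetry), 1e-9)
    fall = max(half * (1.0 + lesion.asymmetry), 1e-9)
    x = l - lesion.center_arclength
    u = np.where(x < 0, x / rise, x / fall)
    b = np.where(np.abs(u) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return b


def radius_profile(total_length: float, base: float, taper: float, lesions=()):
    """Half-width R(l) at 1-px spacing: linear taper times stenosis factors."""
    if not base - taper * total_length > 0:
        raise ValueError("taper removes the whole vessel before its end")
    ls = np.arange(int(np.floor(total_length)) + 1, dtype=float)
    r = base - taper * ls
    for lesion in lesions:
        r = r * (1.0 - lesion.percent_stenosis / 100.0 * _lesion_bump(ls, lesion))
    if np.any(r <= 0):
        raise ValueError("radius profile is non-positive somewhere")
    return r


def render_image(gt: GroundTruth, contrast: float, background: float, shape):
    """Render the projection of a circular lumen along the center-line.

    Pixel intensity is background - contrast*sqrt(1 - (d/R)^2) inside the
    vessel (d = distance to the center-line, R = local half-width) and the
    background level outside.
    """
    h, w = shape
    margin = float(np.max(gt.radii))
    if (
        np.any(gt.points[:, 0] < margin)
        or np.any(gt.points[:, 0] > w - 1 - margin)
        or np.any(gt.points[:, 1] < margin)
        or np.any(gt.points[:, 1] > h - 1 - margin)
    ):
        raise ValueError("center-line too close to the image border for its radius")
    tree = cKDTree(gt.points)
    ys, xs = np.mgrid[0:h, 0:w]
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    dist, idx = tree.query(pix, distance_upper_bound=margin + 1.5)
    img = np.full(h * w, float(background))
    hit = np.isfinite(dist)
    r_local = np.where(hit, gt.radii[np.where(hit, idx, 0)], 1.0)
    inside = hit & (dist < r_local)
    depth = np.sqrt(np.clip(1.0 - (dist[inside] / r_local[inside]) ** 2, 0.0, 1.0))
    img[inside] -= contrast * depth
    return img.reshape(h, w)


def add_gaussian_noise(image, snr_db: float | None, rng_seed: int, contrast: float = DEFAULT_CONTRAST):
    """Additive white Gaussian noise at amplitude-ratio SNR.

    sigma_n = contrast / 10**(snr_db/20); output clipped to [0, 255].
    snr_db=None returns the image unchanged.
    """
    img = np.asarray(image, dtype=float)
    if snr_db is None:
        return img.copy()
    sigma = contrast / 10.0 ** (snr_db / 20.0)
    rng = np.random.default_rng(rng_seed)
    noisy = img + rng.normal(0.0, sigma, size=img.shape)
    return np.clip(noisy, 0.0, 255.0)


def build_phantom(phantom: VesselPhantom, pad: float = 8.0):
    """Realize a phantom: (image, ground truth), image sized to fit the vessel.

    The center-line is generated from the origin along +x, then translated so
    the vessel sits inside the image with a margin of max radius + pad.
    """
    pts, tans = chain_centerline(phantom.arcs)
    radii = radius_profile(phantom.total_length, phantom.base_half_width, phantom.taper, phantom.lesions)
    n = min(len(pts), len(radii))
    pts, tans, radii = pts[:n], tans[:n], radii[:n]
    margin = float(np.max(radii)) + pad
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    pts = pts - lo
    shape = (int(np.ceil(hi[1] - lo[1])) + 1, int(np.ceil(hi[0] - lo[0])) + 1)
    norms = np.linalg.norm(tans, axis=1, keepdims=True)
    gt = GroundTruth(points=pts, tangents=tans / norms, radii=radii)
    clean = render_image(gt, phantom.contrast, phantom.background, shape)
    image = add_gaussian_noise(clean, phantom.snr_db, phantom.rng_seed, phantom.contrast)
    return image, gt


# ---------------------------------------------------------------------------
# The seven-group simulation dataset (86 base phantoms x 4 noise levels = 344)
# ---------------------------------------------------------------------------


def _stenosis(center: float, percent: float, extent: float = 40.0, asym: float = 0.0) -> LesionSpec:
    return LesionSpec(center_arclength=center, percent_stenosis=percent, extent=extent, asymmetry=asym)


def table1_phantoms() -> list[tuple[int, VesselPhantom]]:
    """The 86 base phantoms of the simulation study, as (group, phantom).

    Group 1: 12 straight, taper 0, stenosis 30-95%.
    Group 2: 7 straight, taper 0.00145, stenosis 30-95%.
    Group 3: 23 knee-type (constant-curvature bends 0.003-0.015 1/px,
             arc lengths 50-175 px), taper 0.0008, no stenosis.
    Group 4: 9 single curved segments, taper 0.0008, stenosis 30-95%.
    Group 5: 9 multi-segment (S-shaped), taper 0.001, stenosis 30-95%.
    Group 6: 13 multi-segment with two stenoses, taper 0.
    Group 7: 13 multi-segment with two stenoses, taper 0.00145.
    """
    out: list[tuple[int, VesselPhantom]] = []
    length = 300.0

    # group 1: straight, zero taper, stenosis sweep
    for pct in np.linspace(30.0, 95.0, 12):
        out.append((1, VesselPhantom(
            arcs=(ArcSpec(0.0, length),),
            taper=0.0,
            lesions=(_stenosis(length / 2, float(pct)),),
        )))

    # group 2: straight, medium taper
    for pct in np.linspace(30.0, 95.0, 7):
        out.append((2, VesselPhantom(
            arcs=(ArcSpec(0.0, length),),
            taper=0.00145,
            lesions=(_stenosis(length / 2, float(pct)),),
        )))

    # group 3: knee-type bends, curvature x arc-length grid (first 23 combos)
    curvatures = [0.003, 0.006, 0.009, 0.012, 0.015]
    arc_lengths = [50.0, 81.0, 112.0, 144.0, 175.0]
    knees = [(k, L) for k in curvatures for L in arc_lengths][:23]
    for k, arclen in knees:
        out.append((3, VesselPhantom(
            arcs=(ArcSpec(0.0, 60.0), ArcSpec(k, arclen), ArcSpec(0.0, 60.0)),
            taper=0.0008,
        )))

    # group 4: single curved segment with stenosis, variable curvature
    for i, pct in enumerate(np.linspace(30.0, 95.0, 9)):
        k = 0.002 + 0.001 * (i % 4)
        out.append((4, VesselPhantom(
            arcs=(ArcSpec(k, 250.0),),
            taper=0.0008,
            lesions=(_stenosis(125.0, float(pct)),),
        )))

    # group 5: multi-segment S-curves with stenosis
    for i, pct in enumerate(np.linspace(30.0, 95.0, 9)):
        k = 0.003 + 0.001 * (i % 3)
        out.append((5, VesselPhantom(
            arcs=(ArcSpec(k, 130.0), ArcSpec(-k, 130.0)),
            taper=0.001,
            lesions=(_stenosis(130.0, float(pct)),),
        )))

    # groups 6 and 7: multi-segment, two stenoses, taper 0 / 0.00145
    pairs = [(40.0, 60.0), (50.0, 70.0), (60.0, 80.0), (70.0, 90.0),
             (30.0, 95.0), (45.0, 65.0), (55.0, 75.0), (65.0, 85.0),
             (35.0, 55.0), (75.0, 95.0), (40.0, 80.0), (50.0, 90.0), (60.0, 95.0)]
    for taper, group in ((0.0, 6), (0.00145, 7)):
        for i, (p1, p2) in enumerate(pairs):
            k = 0.002 + 0.0005 * (i % 5)
            asym = 0.3 if i % 2 else 0.0
            out.append((group, VesselPhantom(
                arcs=(ArcSpec(k, 110.0), ArcSpec(-k, 110.0), ArcSpec(k, 80.0)),
                taper=taper,
                lesions=(_stenosis(80.0, p1, asym=asym), _stenosis(220.0, p2, asym=asym)),
            )))

    assert len(out) == 86
    return out


def generate_table1_dataset(out_dir, master_seed: int = 0) -> pd.DataFrame:
    """Write the full synthetic dataset (344 images) and its manifest.

    Each of the 86 base phantoms is rendered noiseless and at SNR 20, 16 and
    10 dB with noise seeds derived deterministically from master_seed.
    Returns the manifest (also written to manifest.csv).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for base_id, (group, phantom) in enumerate(table1_phantoms(), start=1):
        clean, gt = build_phantom(phantom)
        gt_path = out_dir / f"vessel_{base_id:03d}_gt.csv"
        pd.DataFrame({
            "x": gt.points[:, 0],
            "y": gt.points[:, 1],
            "tangent_deg": np.degrees(np.arctan2(gt.tangents[:, 1], gt.tangents[:, 0])),
            "half_width": gt.radii,
        }).to_csv(gt_path, index=False)
        for level_idx, snr in enumerate(SNR_LEVELS_DB):
            seed = (int(master_seed) * 1009 + base_id * 13 + level_idx) % (2**31 - 1)
            img = add_gaussian_noise(clean, snr, seed, phantom.contrast)
            name = f"vessel_{base_id:03d}_snr{'inf' if snr is None else int(snr)}.png"
            iio.imwrite(out_dir / name, np.clip(np.round(img), 0, 255).astype(np.uint8))
            rows.append({
                "image": name,
                "ground_truth": gt_path.name,
                "group": group,
                "base_id": base_id,
                "snr_db": np.inf if snr is None else snr,
                "noise_seed": seed,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
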