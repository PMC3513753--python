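"""File formats: images, center-line CSV + label PNG, seed CSV.

Coordinates in all files are 0-based with x = column and y = row (pixel
centers at integers); directions are degrees from the +x axis.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .seeds import SeedPoint
from .tracer import CenterlineMap, CenterlineSegment, TracePoint

__all__ = [
    "read_image",
    "write_centerlines",
    "read_centerlines",
    "write_seeds",
    "read_seeds",
]

log = logging.getLogger(__name__)

CENTERLINE_COLUMNS = ["segment_id", "point_index", "x", "y", "direction_deg",
                      "half_width", "is_bifurcation"]


def read_image(path) -> np.ndarray:
    """Load a grayscale image as float, preserving its dynamic range.

    RGB(A) input is collapsed to luminance with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"unreadable image file: {path}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        log.warning("collapsing RGB image to luminance: %s", path)
        arr = arr @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise ValueError(f"expected a single-frame 2-D image: {path}")
    return arr.astype(float)


def write_centerlines(segments: list[CenterlineSegment], clmap: CenterlineMap, prefix) -> None:
    """Write <prefix>_centerlines.csv and <prefix>_map.png (16-bit labels)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        bif = set(seg.bifurcations)
        for i, tp in enumerate(seg.points):
            rows.append({
                "segment_id": seg.segment_number,
                "point_index": i,
                "x": tp.position[0],
                "y": tp.position[1],
                "direction_deg": np.degrees(np.arctan2(tp.direction[1], tp.direction[0])),
                "half_width": tp.half_width,
                "is_bifurcation": int(i in bif),
            })
    df = pd.DataFrame(rows, columns=CENTERLINE_COLUMNS)
    df.to_csv(prefix.parent / f"{prefix.name}_centerlines.csv", index=False)
    labels = np.clip(clmap.labels, 0, 2**16 - 1).astype(np.uint16)
    iio.imwrite(prefix.parent / f"{prefix.name}_map.png", labels)


def read_centerlines(prefix):
    """Invert write_centerlines: (segments, map)."""
    prefix = Path(prefix)
    csv_path = prefix.parent / f"{prefix.name}_centerlines.csv"
    df = pd.read_csv(csv_path)
    missing = [c for c in CENTERLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"centerline CSV missing columns {missing}: {csv_path}")
    segments = []
    for seg_id, grp in df.groupby("segment_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = []
        bifs = []
        for _, row in grp.iterrows():
            ang = np.radians(row["direction_deg"])
            pts.append(TracePoint(
                position=np.array([row["x"], row["y"]]),
                direction=np.array([np.cos(ang), np.sin(ang)]),
                half_width=float(row["half_width"]),
            ))
            if int(row["is_bifurcation"]):
                bifs.append(int(row["point_index"]))
        segments.append(CenterlineSegment(points=pts, segment_number=int(seg_id), bifurcations=bifs))
    map_path = prefix.parent / f"{prefix.name}_map.png"
    labels = iio.imread(map_path).astype(np.int32) if map_path.exists() else None
    clmap = CenterlineMap(labels=labels) if labels is not None else None
    return segments, clmap


def write_seeds(seeds: list[SeedPoint], path) -> None:
    pd.DataFrame([{
        "x": s.position[0], "y": s.position[1],
        "dir_x": s.direction[0], "dir_y": s.direction[1],
        "half_width": s.half_width,
    } for s in seeds]).to_csv(path, index=False)


def read_seeds(path) -> list[SeedPoint]:
    df = pd.read_csv(path)
    required = {"x", "y", "dir_x", "dir_y", "half_width"}
    if not required.issubset(df.columns):
        raise ValueError(f"seed CSV must have columns {sorted(required)}")
    seeds = []
    for _, row in df.iterrows():
        d = np.array([row["dir_x"], row["dir_y"]], dtype=float)
        seeds.append(SeedPoint(
            position=np.array([row["x"], row["y"]], dtype=float),
            direction=d / np.linalg.norm(d),
            half_width=float(row["half_width"]),
        ))
    return seeds
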