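"""Evaluation metrics for estimated center-lines.

Against an analytic reference with tangents the package reports the
normalized global distance error dNorm = (1/N) sum d_i^2/r_i^2 and the mean
square / root-mean-square orientation error, with correspondences taken
along the perpendicular to the reference tangent (not closest-point).
Against unstructured point sets it reports delta-disk correspondence
quantities: spatial discrepancy mu, the mutual consistency pair
(alpha_AG, alpha_GA), their harmonic mean F1, and the coverage-based success
rate (coverage < 60% counts as divergence).  The silhouette-based
false-detection measure epsilon_F scores dense vesselness maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import GroundTruth

__all__ = [
    "CorrespondenceSets",
    "MetricsReport",
    "perpendicular_correspondence",
    "normalized_distance_error",
    "orientation_error",
    "correspondence_sets",
    "discrepancy",
    "consistency_f1",
    "success_rate",
    "false_detection_measure",
    "evaluate_centerlines",
    "evaluate_segments",
    "DIVERGENCE_COVERAGE",
]

#: coverage below this percentage counts as divergence
DIVERGENCE_COVERAGE = 60.0
#: default disk radius (px) for discrepancy / consistency reporting
DELTA_REPORT = 5.0
#: stricter disk radius (px) used inside the success-rate coverage
DELTA_COVERAGE = 2.0


@dataclass(frozen=True)
class CorrespondenceSets:
    """delta-disk correspondences between point sets A and G."""

    a_mask: np.ndarray     # A_g membership
    g_mask: np.ndarray     # G_a membership
    a_links: np.ndarray    # index into G of C_g(a), -1 where unmatched
    g_links: np.ndarray    # index into A of C_a(g), -1 where unmatched
    a_dist: np.ndarray
    g_dist: np.ndarray


@dataclass(frozen=True)
class MetricsReport:
    d_norm: float
    orientation_mse: float
    orientation_rmse: float
    discrepancy_mu: float
    alpha_ag: float
    alpha_ga: float
    f1: float
    coverage: float
    diverged: bool
    n_matched: int

    def to_dict(self) -> dict:
        return {
            "d_norm": self.d_norm,
            "orientation_mse_deg2": self.orientation_mse,
            "orientation_rmse_deg": self.orientation_rmse,
            "discrepancy_mu_px": self.discrepancy_mu,
            "alpha_ag_pct": self.alpha_ag,
            "alpha_ga_pct": self.alpha_ga,
            "f1_pct": self.f1,
            "coverage_pct": self.coverage,
            "diverged": self.diverged,
            "n_matched": self.n_matched,
        }


def _as_polylines(est) -> list[np.ndarray]:
    if isinstance(est, np.ndarray):
        return [est] if len(est) else []
    return [np.asarray(p, dtype=float) for p in est if len(p)]


def perpendicular_correspondence(ref: GroundTruth, est, window_radii: float = 3.0):
    """Per-reference-point correspondence along the local perpendicular.

    For each reference point p_i with tangent t_i the estimated polyline(s)
    are intersected with the line through p_i perpendicular to t_i, within a
    lateral window of +-window_radii * r_i; d_i is the distance to the
    nearest intersection and O_i the tangent angle difference there (degrees,
    folded to <= 90).  Returns (d, r, O, matched) arrays over all reference
    points; unmatched entries hold NaN.
    """
    polylines = _as_polylines(est)
    n = len(ref.points)
    d = np.full(n, np.nan)
    o = np.full(n, np.nan)
    matched = np.zeros(n, dtype=bool)
    for i in range(n):
        p = ref.points[i]
        t = ref.tangents[i]
        limit = window_radii * ref.radii[i]
        best = np.inf
        best_o = np.nan
        for poly in polylines:
            if len(poly) < 2:
                continue
            s = (poly - p) @ t  # signed distance along the tangent axis
            cross = s[:-1] * s[1:] <= 0
            idx = np.nonzero(cross & ((s[:-1] != 0) | (s[1:] != 0)))[0]
            for j in idx:
                denom = s[j] - s[j + 1]
                f = s[j] / denom if denom != 0 else 0.0
                x = poly[j] + f * (poly[j + 1] - poly[j])
                dist = float(np.linalg.norm(x - p))
                if dist <= limit and dist < best:
                    seg = poly[j + 1] - poly[j]
                    ang = np.degrees(np.arctan2(seg[1], seg[0]) - np.arctan2(t[1], t[0]))
                    ang = abs(((ang + 90.0) % 180.0) - 90.0)
                    best = dist
                    best_o = ang
        if np.isfinite(best):
            d[i] = best
            o[i] = best_o
            matched[i] = True
    return d, ref.radii.copy(), o, matched


def normalized_distance_error(d: np.ndarray, r: np.ndarray, matched: np.ndarray | None = None) -> float:
    """dNorm = (1/N) sum d_i^2 / r_i^2 over matched reference points."""
    if matched is None:
        matched = np.isfinite(d)
    if not np.any(matched):
        return np.nan
    return float(np.mean(d[matched] ** 2 / r[matched] ** 2))


def orientation_error(o: np.ndarray, matched: np.ndarray | None = None):
    """(MSE in degrees^2, RMSE in degrees) of the orientation differences."""
    if matched is None:
        matched = np.isfinite(o)
    if not np.any(matched):
        return np.nan, np.nan
    mse = float(np.mean(o[matched] ** 2))
    return mse, float(np.sqrt(mse))


def correspondence_sets(A, G, delta: float) -> CorrespondenceSets:
    """delta-disk nearest-neighbor correspondences (strict inequality)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    A = np.atleast_2d(np.asarray(A, dtype=float)) if len(A) else np.zeros((0, 2))
    G = np.atleast_2d(np.asarray(G, dtype=float)) if len(G) else np.zeros((0, 2))
    if len(G) and len(A):
        da, ia = cKDTree(G).query(A)
        dg, ig = cKDTree(A).query(G)
    else:
        da, ia = np.full(len(A), np.inf), np.full(len(A), -1, dtype=int)
        dg, ig = np.full(len(G), np.inf), np.full(len(G), -1, dtype=int)
    a_mask = da < delta
    g_mask = dg < delta
    return CorrespondenceSets(
        a_mask=a_mask, g_mask=g_mask,
        a_links=np.where(a_mask, ia, -1), g_links=np.where(g_mask, ig, -1),
        a_dist=da, g_dist=dg,
    )


def discrepancy(A, G, delta: float = DELTA_REPORT) -> float:
    """Spatial discrepancy mu (px): symmetric mean matched distance / 2 + / 2."""
    c = correspondence_sets(A, G, delta)
    if not np.any(c.a_mask) or not np.any(c.g_mask):
        return np.nan
    return float(0.5 * np.mean(c.a_dist[c.a_mask]) + 0.5 * np.mean(c.g_dist[c.g_mask]))


def consistency_f1(A, G, delta: float = DELTA_REPORT):
    """(alpha_AG, alpha_GA, F1) in percent.

    alpha_AG = 100 |A_g|/|A| penalizes false traces; alpha_GA = 100 |G_a|/|G|
    measures completeness; F1 is their harmonic mean.
    """
    if len(G) == 0:
        raise ValueError("reference set G must be non-empty")
    if len(A) == 0:
        return 0.0, 0.0, 0.0
    c = correspondence_sets(A, G, delta)
    a_ag = 100.0 * np.count_nonzero(c.a_mask) / len(A)
    a_ga = 100.0 * np.count_nonzero(c.g_mask) / len(G)
    f1 = 0.0 if (a_ag + a_ga) == 0 else 2.0 * a_ag * a_ga / (a_ag + a_ga)
    return float(a_ag), float(a_ga), float(f1)


def success_rate(est, ref, delta: float = DELTA_COVERAGE):
    """(coverage %, diverged) of the reference by the estimate.

    Coverage is the percentage of reference points with an estimated point
    within delta; below 60% the trace counts as diverged.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if len(ref) == 0:
        raise ValueError("reference must be non-empty")
    est_pts = np.concatenate(_as_polylines(est)) if _as_polylines(est) else np.zeros((0, 2))
    if len(est_pts) == 0:
        return 0.0, True
    c = correspondence_sets(est_pts, ref, delta)
    coverage = 100.0 * np.count_nonzero(c.g_mask) / len(ref)
    return float(coverage), bool(coverage < DIVERGENCE_COVERAGE)


def false_detection_measure(vesselness_img: np.ndarray, silhouette: np.ndarray) -> float:
    """Normalized false detections epsilon_F = (F_p + F_n) / 2N.

    F_p counts strictly positive vesselness outside the silhouette; F_n
    counts zero vesselness inside it.
    """
    v = np.asarray(vesselness_img, dtype=float)
    s = np.asarray(silhouette).astype(bool)
    if v.shape != s.shape:
        raise ValueError("vesselness image and silhouette shapes differ")
    fp = np.count_nonzero((v > 0) & ~s)
    fn = np.count_nonzero(s & (v == 0))
    return float((fp + fn) / (2.0 * v.size))


def evaluate_centerlines(est, ref: GroundTruth, delta: float = DELTA_REPORT,
                         coverage_delta: float = DELTA_COVERAGE,
                         est_pixels=None) -> MetricsReport:
    """Full metric suite of an estimated center-line against analytic truth.

    *est* holds the sub-pixel trace polylines (used for the perpendicular
    distance/orientation errors); *est_pixels*, when given, holds the
    rasterized center-line map pixels used for the point-set measures
    (discrepancy, consistency, coverage), matching their map-based
    definitions.  Without it the polyline points serve both purposes.
    """
    d, r, o, matched = perpendicular_correspondence(ref, est)
    mse, rmse = orientation_error(o, matched)
    point_source = est_pixels if est_pixels is not None else est
    est_pts = np.concatenate(_as_polylines(point_source)) if _as_polylines(point_source) else np.zeros((0, 2))
    mu = discrepancy(est_pts, ref.points, delta) if len(est_pts) else np.nan
    if len(est_pts):
        a_ag, a_ga, f1 = consistency_f1(est_pts, ref.points, delta)
    else:
        a_ag = a_ga = f1 = 0.0
    coverage, diverged = success_rate(est_pts, ref.points, coverage_delta)
    return MetricsReport(
        d_norm=normalized_distance_error(d, r, matched),
        orientation_mse=mse,
        orientation_rmse=rmse,
        discrepancy_mu=mu,
        alpha_ag=a_ag,
        alpha_ga=a_ga,
        f1=f1,
        coverage=coverage,
        diverged=diverged,
        n_matched=int(np.count_nonzero(matched)),
    )


def evaluate_segments(segments, ref: GroundTruth, delta: float = DELTA_REPORT,
                      coverage_delta: float = DELTA_COVERAGE) -> MetricsReport:
    """Evaluate traced segments: polylines for the perpendicular errors,
    rasterized map pixels for the point-set measures."""
    polylines = [np.array([tp.position for tp in s.points]) for s in segments]
    pixels = [s.pixels.astype(float) for s in segments if s.pixels is not None]
    return evaluate_centerlines(polylines, ref, delta, coverage_delta,
                                est_pixels=pixels if pixels else None)
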