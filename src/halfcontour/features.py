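"""Contour shape features for tumor classification.

Six parameters quantify the irregularity of a tumor boundary:

* **TC** (tumor circularity) ``P^2 / A`` — perimeter squared over area, the
  isoperimetric quotient; minimized by a disk, grows with boundary roughness.
* **NRL_M / NRL_STD** — mean and sample standard deviation of the normalized
  radial length (contour-pixel distances to the region centroid, divided by
  their maximum).
* **AR** (area ratio) — one-sided average excess of the normalized radial
  length above its mean; the fraction of the shape protruding beyond the
  mean-radius circle.
* **RI** (roughness index) — mean absolute difference between consecutive
  normalized radial lengths; fine-scale spiculation.
* **SDD** (standard deviation of degree) — population standard deviation of
  the vertex angles formed at each contour pixel with its neighbors at offset
  ±k along the contour; the half-contour irregularity statistic.

Features can be computed on the full closed contour or on the **half
contour**: the upper arc between the leftmost and rightmost contour pixels,
closed by the chord joining them.  The upper arc is much less affected by
posterior acoustic shadowing than the lower one, which is the point of the
half-contour mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as bresenham_line

from .segmentation import Contour

__all__ = [
    "HalfContour",
    "ClosedRegionMetrics",
    "RadialProfile",
    "AngleSeries",
    "FeatureVector",
    "FEATURE_NAMES",
    "split_half_contour",
    "close_and_measure",
    "tumor_circularity",
    "radial_profile",
    "nrl_features",
    "vertex_angles",
    "sdd",
    "feature_vector",
]

FEATURE_NAMES = ("tc", "nrl_m", "nrl_std", "ar", "ri", "sdd")


@dataclass
class HalfContour:
    """Upper arc from the leftmost to the rightmost contour pixel, plus the
    rasterized chord joining them."""

    arc: np.ndarray  # (N, 2) ordered (x, y), open, from p_left to p_right
    p_left: tuple[int, int]
    p_right: tuple[int, int]
    chord: np.ndarray  # (K, 2) Bresenham pixels of the closing chord


@dataclass(frozen=True)
class ClosedRegionMetrics:
    """Pixel-count perimeter and area of a closed digital region."""

    perimeter_px: int
    area_px: int

    def __post_init__(self) -> None:
        if self.perimeter_px < 4:
            raise ValueError("perimeter must be >= 4 pixels")
        if self.area_px < 1:
            raise ValueError("area must be >= 1 pixel")


@dataclass
class RadialProfile:
    """Distances from contour pixels to the region centroid, raw and
    normalized by their maximum (so max(d_hat) == 1 exactly)."""

    d: np.ndarray
    d_hat: np.ndarray
    centroid: tuple[float, float]  # (x, y)


@dataclass
class AngleSeries:
    """Vertex angles (degrees) at each contour pixel, offset k."""

    theta: np.ndarray
    k: int


@dataclass
class FeatureVector:
    tc: float
    nrl_m: float
    nrl_std: float
    ar: float
    ri: float
    sdd: float
    mode: str  # "full" | "half"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _lexi_extreme(points: np.ndarray, rightmost: bool) -> int:
    """Index of the leftmost (or rightmost) point; ties go to smaller y."""
    x = points[:, 0]
    y = points[:, 1]
    if rightmost:
        key_x = -x
    else:
        key_x = x
    order = np.lexsort((y, key_x))
    return int(order[0])


def split_half_contour(
    contour: Contour, exclusion: tuple[int, int] | None = None
) -> HalfContour:
    """Split a closed contour at its leftmost/rightmost pixels and return the
    upper arc together with the chord joining the two endpoints.

    ``exclusion`` is an inclusive column interval ``(a, b)``; contour pixels
    with a <= x <= b are ignored when locating the endpoints (manual exclusion
    of a laterally shadowed portion), but the arc itself is taken from the
    full contour.
    """
    pts = np.asarray(contour.points)
    if len(pts) < 8 or not contour.closed:
        raise ValueError("need a closed contour with at least 8 pixels")
    if exclusion is not None:
        a, b = exclusion
        allowed = ~((pts[:, 0] >= a) & (pts[:, 0] <= b))
        if not allowed.any():
            raise ValueError("exclusion removes the entire contour")
        cand = pts[allowed]
    else:
        allowed = np.ones(len(pts), dtype=bool)
        cand = pts
    il_c = _lexi_extreme(cand, rightmost=False)
    ir_c = _lexi_extreme(cand, rightmost=True)
    p_left = tuple(int(v) for v in cand[il_c])
    p_right = tuple(int(v) for v in cand[ir_c])
    # locate these pixels in the full ordered sequence
    idx_l = int(np.flatnonzero((pts[:, 0] == p_left[0]) & (pts[:, 1] == p_left[1]))[0])
    rolled = np.roll(pts, -idx_l, axis=0)
    pos_r = int(
        np.flatnonzero((rolled[:, 0] == p_right[0]) & (rolled[:, 1] == p_right[1]))[0]
    )
    arc_a = rolled[: pos_r + 1]  # P_l -> P_r
    arc_b = np.concatenate([rolled[pos_r:], rolled[:1]], axis=0)  # P_r -> P_l
    if arc_a[:, 1].mean() <= arc_b[:, 1].mean():
        arc = arc_a
    else:
        arc = arc_b[::-1]  # reorient left-to-right, P_l -> P_r
    rr, cc = bresenham_line(p_left[1], p_left[0], p_right[1], p_right[0])
    chord = np.stack([cc, rr], axis=1).astype(np.int64)
    return HalfContour(arc=arc.copy(), p_left=p_left, p_right=p_right, chord=chord)


def _boundary_pixels(obj: Contour | HalfContour) -> np.ndarray:
    """Deduplicated boundary pixel set: contour points, or arc ∪ chord."""
    if isinstance(obj, Contour):
        pts = np.asarray(obj.points)
    else:
        pts = np.concatenate([np.asarray(obj.arc), np.asarray(obj.chord)], axis=0)
    return np.unique(pts, axis=0)


def _fill_boundary(boundary: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a closed boundary pixel set and fill its interior.

    Returns (filled bool mask, (x0, y0) origin of the mask in image coords).
    The 8-connected boundary separates the 4-connected background, so the
    standard hole fill recovers the enclosed pixels.
    """
    x0, y0 = boundary[:, 0].min() - 1, boundary[:, 1].min() - 1
    w = boundary[:, 0].max() - x0 + 2
    h = boundary[:, 1].max() - y0 + 2
    grid = np.zeros((h, w), dtype=bool)
    grid[boundary[:, 1] - y0, boundary[:, 0] - x0] = True
    filled = ndi.binary_fill_holes(grid)
    return filled, (int(x0), int(y0))


def close_and_measure(obj: Contour | HalfContour) -> ClosedRegionMetrics:
    """Pixel-count perimeter and enclosed area of a closed curve.

    The perimeter is the number of distinct boundary pixels (for a half
    contour: arc plus closing chord); the area counts every pixel enclosed by
    the curve, boundary included.
    """
    boundary = _boundary_pixels(obj)
    filled, _ = _fill_boundary(boundary)
    area = int(filled.sum())
    perim = int(len(boundary))
    if area < perim:
        raise ValueError("degenerate contour: no enclosed interior")
    return ClosedRegionMetrics(perimeter_px=perim, area_px=area)


def tumor_circularity(m: ClosedRegionMetrics) -> float:
    """TC = perimeter^2 / area."""
    if m.area_px <= 0:
        raise ValueError("area must be positive")
    return m.perimeter_px**2 / m.area_px


def region_centroid(obj: Contour | HalfContour) -> tuple[float, float]:
    """Mass center (x, y) of the pixels enclosed by the (chord-closed) curve."""
    boundary = _boundary_pixels(obj)
    filled, (x0, y0) = _fill_boundary(boundary)
    rr, cc = np.nonzero(filled)
    return (float(cc.mean() + x0), float(rr.mean() + y0))


def radial_profile(
    obj: Contour | HalfContour, boundary: np.ndarray | None = None
) -> RadialProfile:
    """Distances from the ordered boundary pixels to the region centroid.

    For a half contour the centroid is that of the chord-closed half region
    and the profile runs over the open arc only.  A centroid falling outside
    the region (possible for crescents) only triggers a warning.
    """
    cx, cy = region_centroid(obj)
    if boundary is None:
        boundary = obj.points if isinstance(obj, Contour) else obj.arc
    boundary = np.asarray(boundary, dtype=np.float64)
    d = np.hypot(boundary[:, 0] - cx, boundary[:, 1] - cy)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("degenerate boundary: all pixels at the centroid")
    filled, (x0, y0) = _fill_boundary(_boundary_pixels(obj))
    ix, iy = int(round(cx)) - x0, int(round(cy)) - y0
    if not (0 <= iy < filled.shape[0] and 0 <= ix < filled.shape[1] and filled[iy, ix]):
        warnings.warn("region centroid falls outside the region", stacklevel=2)
    return RadialProfile(d=d, d_hat=d / dmax, centroid=(cx, cy))


def nrl_features(
    profile: RadialProfile | np.ndarray, closed: bool = True
) -> tuple[float, float, float, float]:
    """Normalized-radial-length statistics: (NRL_M, NRL_STD, AR, RI).

    NRL_M is the mean of the normalized lengths; NRL_STD their sample standard
    deviation (1/(N-1)); AR sums only the positive excesses above the mean,
    scaled by 1/(mean*N); RI averages absolute consecutive differences — with
    wraparound for a closed contour (N terms), over the N-1 open-arc gaps
    otherwise.
    """
    d_hat = profile.d_hat if isinstance(profile, RadialProfile) else np.asarray(profile)
    d_hat = np.asarray(d_hat, dtype=np.float64)
    n = len(d_hat)
    if n < 3:
        raise ValueError("need at least 3 contour pixels")
    d_bar = d_hat.mean()
    nrl_std = float(np.sqrt(np.sum((d_hat - d_bar) ** 2) / (n - 1)))
    excess = np.where(d_hat > d_bar, d_hat - d_bar, 0.0)
    ar = float(excess.sum() / (d_bar * n))
    if closed:
        ri = float(np.abs(d_hat - np.roll(d_hat, -1)).sum() / n)
    else:
        ri = float(np.abs(np.diff(d_hat)).sum() / (n - 1))
    return float(d_bar), nrl_std, ar, ri


def vertex_angles(
    boundary: np.ndarray, k: int = 5, closed: bool = True
) -> AngleSeries:
    """Angle (degrees) at each boundary pixel between the vectors to its
    k-th predecessor and k-th successor along the boundary.

    Closed boundaries wrap indices; open ones yield angles only where both
    neighbors exist.  Coincident points produce undefined angles and are
    skipped with a warning.
    """
    pts = np.asarray(boundary, dtype=np.float64)
    n = len(pts)
    if k < 1:
        raise ValueError("offset k must be >= 1")
    if n <= 2 * k:
        raise ValueError("need more than 2k boundary pixels")
    if closed:
        prev_pts = np.roll(pts, k, axis=0)
        next_pts = np.roll(pts, -k, axis=0)
        center = pts
    else:
        center = pts[k : n - k]
        prev_pts = pts[: n - 2 * k]
        next_pts = pts[2 * k :]
    u = prev_pts - center
    v = next_pts - center
    nu = np.hypot(u[:, 0], u[:, 1])
    nv = np.hypot(v[:, 0], v[:, 1])
    ok = (nu > 0) & (nv > 0)
    if not ok.all():
        warnings.warn("skipping angles at coincident points", stacklevel=2)
    cosang = np.clip(
        (u[ok] * v[ok]).sum(axis=1) / (nu[ok] * nv[ok]), -1.0, 1.0
    )
    theta = np.degrees(np.arccos(cosang))
    return AngleSeries(theta=theta, k=k)


def sdd(angles: AngleSeries | np.ndarray) -> float:
    """Standard deviation of degree: population std (1/N) of the vertex
    angles, in degrees."""
    theta = angles.theta if isinstance(angles, AngleSeries) else np.asarray(angles)
    if len(theta) < 2:
        raise ValueError("need at least 2 angles")
    return float(np.sqrt(np.mean((theta - theta.mean()) ** 2)))


def feature_vector(
    contour: Contour,
    mode: str = "full",
    k: int = 5,
    exclusion: tuple[int, int] | None = None,
) -> FeatureVector:
    """Compute all six features for a closed contour in full or half mode.

    Full mode uses the closed contour for everything.  Half mode closes the
    upper arc with its chord for perimeter, area and centroid, and uses the
    open arc for the sequential statistics (RI, SDD).
    """
    if mode not in ("full", "half"):
        raise ValueError("mode must be 'full' or 'half'")
    if mode == "full":
        obj: Contour | HalfContour = contour
        ordered = np.asarray(contour.points)
        closed = True
    else:
        obj = split_half_contour(contour, exclusion=exclusion)
        ordered = np.asarray(obj.arc)
        closed = False
    metrics = close_and_measure(obj)
    tc = tumor_circularity(metrics)
    profile = radial_profile(obj, boundary=ordered)
    nrl_m, nrl_std, ar, ri = nrl_features(profile, closed=closed)
    theta = vertex_angles(ordered, k=k, closed=closed)
    return FeatureVector(
        tc=tc, nrl_m=nrl_m, nrl_std=nrl_std, ar=ar, ri=ri, sdd=sdd(theta), mode=mode
    )
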