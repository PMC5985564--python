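"""Radial normalization of droplet positions against an irregular root edge.

Every droplet is recentred on the manually marked slice center, expressed
in polar coordinates, and projected onto the edge contour along its own
polar angle: the relative distance

    pp = 100 * r_CD / r_CE

is the droplet's center distance as a percent of the center-to-edge
distance along the same ray. pp is then binned into nine equal-width
classes (class 1 innermost, class 9 the outer cell layers). Because root
slices are rarely circular — often oval, sometimes with coves — r_CE is
computed by exact ray/polygon-segment intersection, taking the farthest
intersection so pp stays monotone in r_CD and bounded by 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask

from .errors import ConsistencyError, DomainError, GeometryError

__all__ = [
    "ClassBinning",
    "SliceGeometry",
    "RadialRecord",
    "recenter",
    "radius",
    "polar_angle",
    "edge_radius_at_angle",
    "edge_radius_profile",
    "relative_distance",
    "assign_class",
    "map_droplets",
    "relative_distance_map",
]

N_CLASSES = 9
#: pp above 100 up to this value is clamped to the edge (segmentation halo);
#: beyond it the center/edge pairing is considered wrong.
CLAMP_MAX_DEFAULT = 105.0


@dataclass(frozen=True)
class ClassBinning:
    """Nine equal-width bins of pp over [0, 100].

    Intervals are half-open with the top class closed at 100:
    class k covers [100(k-1)/9, 100k/9) for k < 9 and [800/9, 100] for
    k = 9. Exact multiples of 100/9 belong to the upper class.
    """

    n_classes: int = N_CLASSES

    @property
    def boundaries(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_classes + 1)


@dataclass
class SliceGeometry:
    """Manually marked center plus the ordered closed edge contour.

    Parameters
    ----------
    center : (x_C, y_C) in px.
    edge : (N, 2) array of x-y vertices, ordered, closed implicitly
        (first vertex not repeated), N >= 16.
    scale : µm per px, > 0.
    """

    center: tuple[float, float]
    edge: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.edge = np.asarray(self.edge, dtype=np.float64)
        if self.edge.ndim != 2 or self.edge.shape[1] != 2 or self.edge.shape[0] < 16:
            raise GeometryError("edge must be an (N>=16, 2) vertex array")
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise GeometryError("scale must be finite and positive")
        poly = Polygon(self.edge)
        if not poly.is_valid:
            poly = poly.buffer(0)  # cleanup of rasterization self-touches
            if poly.geom_type != "Polygon" or not poly.is_valid:
                raise GeometryError("edge polygon is not simple after cleanup")
        if not poly.contains(Point(self.center)):
            raise GeometryError("center does not lie strictly inside the edge polygon")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon


def recenter(point: tuple[float, float], center: tuple[float, float]) -> tuple[float, float]:
    """Shift a point into the center-origin frame: (x_i - x_C, y_i - y_C)."""
    return point[0] - center[0], point[1] - center[1]


def radius(x_mod: float, y_mod: float) -> float:
    """Euclidean distance from the center, in px."""
    return math.hypot(x_mod, y_mod)


def polar_angle(x_mod: float, y_mod: float) -> float:
    """Polar angle in [0, 2π) of a recentred point.

    arccos(x/r) on the closed upper half-plane (y >= 0), extended to the
    full circle by 2π − arccos(x/r) for y < 0. Equal to atan2(y, x) mod 2π.
    """
    r = math.hypot(x_mod, y_mod)
    if r == 0:
        raise GeometryError("polar angle undefined at the center")
    a = math.acos(max(-1.0, min(1.0, x_mod / r)))
    phi = a if y_mod >= 0 else 2.0 * math.pi - a
    return phi % (2.0 * math.pi)


def _ray_radii(rel_edge: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Farthest ray/polygon intersection distance for each angle.

    rel_edge : (N, 2) polygon vertices relative to the center.
    phis : (M,) angles. Returns (M,) distances.
    """
    p = rel_edge
    q = np.roll(rel_edge, -1, axis=0)
    e = q - p  # (N, 2) segment vectors
    d = np.stack([np.cos(phis), np.sin(phis)], axis=1)  # (M, 2)
    # cross products, broadcast (M, N)
    denom = d[:, 0:1] * e[None, :, 1] - d[:, 1:2] * e[None, :, 0]  # d × e
    pxe = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]  # p × e, (N,)
    pxd = p[None, :, 0] * d[:, 1:2] - p[None, :, 1] * d[:, 0:1]  # p × d, (M, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = pxe[None, :] / denom
        s = pxd / denom
    valid = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    t = np.where(valid, t, -np.inf)
    r = t.max(axis=1)
    if np.any(~np.isfinite(r)):
        raise GeometryError("ray from center misses the edge polygon")
    return r


def edge_radius_at_angle(geometry: SliceGeometry, phi: float | np.ndarray) -> float | np.ndarray:
    """Distance from the center to the edge along the ray at angle ``phi``.

    The ray is intersected with every polygon segment; the farthest
    intersection is returned, so for coved (non-star-shaped) contours a
    droplet sitting in a cove gets pp < 100.
    """
    rel = geometry.edge - np.asarray(geometry.center, dtype=np.float64)
    phis = np.atleast_1d(np.asarray(phi, dtype=np.float64))
    r = _ray_radii(rel, phis)
    return float(r[0]) if np.isscalar(phi) or np.ndim(phi) == 0 else r


def edge_radius_profile(geometry: SliceGeometry, n_angles: int = 2048) -> np.ndarray:
    """r_CE sampled at ``n_angles`` uniformly spaced angles over [0, 2π)."""
    phis = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    rel = geometry.edge - np.asarray(geometry.center, dtype=np.float64)
    out = np.empty(n_angles)
    step = 256  # chunked to bound the (angles × segments) broadcast
    for i in range(0, n_angles, step):
        out[i : i + step] = _ray_radii(rel, phis[i : i + step])
    return out


def relative_distance(
    r_cd: float, r_ce: float, clamp_max: float = CLAMP_MAX_DEFAULT
) -> float:
    """Relative droplet distance pp = 100·r_CD/r_CE in percent.

    Droplets marginally outside the contour (segmentation halo) with
    pp in (100, clamp_max] are clamped to 100 with a warning; larger pp
    signals a wrong center/edge pairing and raises ConsistencyError.
    """
    if r_ce <= 0:
        raise GeometryError("edge radius must be positive")
    pp = 100.0 * r_cd / r_ce
    if pp > clamp_max:
        raise ConsistencyError(
            f"pp = {pp:.2f} > {clamp_max}: droplet far outside the edge"
        )
    if pp > 100.0:
        warnings.warn(f"pp = {pp:.2f} clamped to 100", stacklevel=2)
        pp = 100.0
    return pp


def assign_class(pp: float, binning: ClassBinning | None = None) -> int:
    """Bin pp into one of nine classes (1 innermost .. 9 at the edge).

    class = min(floor(pp·9/100), 8) + 1: half-open intervals with the top
    class closed at 100.
    """
    n = (binning or ClassBinning()).n_classes
    if not 0.0 <= pp <= 100.0:
        raise DomainError(f"pp = {pp} outside [0, 100]")
    return min(int(math.floor(pp * n / 100.0)), n - 1) + 1


@dataclass(frozen=True)
class RadialRecord:
    """Full radial bookkeeping for one droplet."""

    droplet_id: int
    x_mod: float
    y_mod: float
    r_cd: float
    phi: float
    r_ce: float
    pp: float
    class_index: int


def map_droplets(
    points: np.ndarray,
    geometry: SliceGeometry,
    clamp_max: float = CLAMP_MAX_DEFAULT,
    binning: ClassBinning | None = None,
) -> list[RadialRecord]:
    """Map droplet centroids to radial records.

    points : (M, 2) array of droplet (x, y) centroids in px.
    Droplets exactly at the center get pp = 0, class 1 (the polar angle is
    undefined there but the relative distance is not).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    records: list[RadialRecord] = []
    for i, (x, y) in enumerate(pts):
        x_mod, y_mod = recenter((x, y), geometry.center)
        r_cd = radius(x_mod, y_mod)
        if r_cd == 0.0:
            records.append(RadialRecord(i, 0.0, 0.0, 0.0, 0.0, float("nan"), 0.0, 1))
            continue
        phi = polar_angle(x_mod, y_mod)
        r_ce = float(edge_radius_at_angle(geometry, phi))
        pp = relative_distance(r_cd, r_ce, clamp_max=clamp_max)
        records.append(
            RadialRecord(i, x_mod, y_mod, r_cd, phi, r_ce, pp, assign_class(pp, binning))
        )
    return records


def rasterize(geometry: SliceGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers inside the edge polygon.

    Rasterization cost scales with vertex count; a 0.2 px polygon
    simplification changes class areas by far less than the pixel-center
    binning itself.
    """
    ext = geometry.polygon.simplify(0.2, preserve_topology=True).exterior
    poly_xy = np.asarray(ext.coords)[:-1]
    return polygon2mask(shape, poly_xy[:, ::-1])  # polygon given as (row, col)


def relative_distance_map(
    geometry: SliceGeometry,
    shape: tuple[int, int],
    n_angles: int = 2048,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel pp map and per-class pixel counts / areas.

    For every pixel whose center lies inside the edge polygon, pp of the
    pixel center is computed against r_CE interpolated from a dense
    angular profile; pixels outside are NaN. Class areas in mm² are the
    per-class pixel counts times (scale/1000)².

    Returns
    -------
    pp_map : (H, W) float array, NaN outside the polygon.
    counts : (9,) pixel counts per class; sums exactly to the number of
        inside pixels (partition property).
    areas_mm2 : (9,) class areas in mm².
    """
    h, w = shape
    inside = rasterize(geometry, shape)
    prof = edge_radius_profile(geometry, n_angles)
    yy, xx = np.nonzero(inside)
    dx = xx - geometry.center[0]
    dy = yy - geometry.center[1]
    r = np.hypot(dx, dy)
    phi = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
    # periodic linear interpolation of the radius profile
    pos = phi / (2.0 * math.pi) * n_angles
    i0 = np.floor(pos).astype(np.intp) % n_angles
    i1 = (i0 + 1) % n_angles
    frac = pos - np.floor(pos)
    r_ce = prof[i0] * (1.0 - frac) + prof[i1] * frac
    pp = np.clip(100.0 * r / np.maximum(r_ce, 1e-9), 0.0, 100.0)

    pp_map = np.full((h, w), np.nan)
    pp_map[yy, xx] = pp
    n = N_CLASSES
    cls = np.minimum((pp * n / 100.0).astype(np.intp), n - 1)
    counts = np.bincount(cls, minlength=n).astype(np.int64)
    areas_mm2 = counts * (geometry.scale / 1000.0) ** 2
    return pp_map, counts, areas_mm2
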