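"""Radial bladder-wall displacement between pre- and post-void surfaces.

The wall-motion model is radial and separable: in a spherical frame anchored
at the centre of the post-void bladder volume, the displacement of the wall
point in direction (theta, phi) is

    d_r(theta, phi, t) = d0(theta, phi) * alpha(t),      d_theta = d_phi = 0,

where d0 is the total pre-to-post displacement and alpha(t) the dimensionless
time-dependence (module :mod:`vesica.temporal`). d0 is measured by casting a
ray from the origin along each sample direction into both surfaces with the
Moller-Trumbore ray-triangle intersection algorithm and differencing the hit
distances. The wall is partitioned into anterior/posterior, dome/base and
left/right halves for regional statistics and a left-right asymmetry ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .mesh import SurfaceMesh, mesh_centroid

__all__ = [
    "SphericalFrame",
    "DisplacementField",
    "RegionalStats",
    "ray_triangle_intersect",
    "radial_distance",
    "compute_displacement_field",
    "partition_regions",
    "regional_stats",
    "asymmetry_ratio",
    "displacement_density",
    "DensityEstimate",
]

_EPS = 1e-9
_TIE = 1e-12  # boundary-plane tie tolerance for region labels

REGION_NAMES = ("anterior", "posterior", "dome", "base", "left", "right")


# ---------------------------------------------------------------------------
# spherical frame
# ---------------------------------------------------------------------------

@dataclass
class SphericalFrame:
    """Bladder-centric spherical coordinate frame.

    ``origin`` is the volume centroid of the post-void bladder. ``axes`` is a
    right-handed orthonormal triad stored as rows in world coordinates:
    row 0 = x (subject-left), row 1 = y (anterior), row 2 = z (dome/superior).
    theta is the polar angle from +z, phi the azimuth from +x.
    """

    origin: np.ndarray
    axes: np.ndarray = dc_field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal (within 1e-9)")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame axes must be right-handed")

    @classmethod
    def from_meshes(cls, pre: SurfaceMesh, post: SurfaceMesh, axes=None) -> "SphericalFrame":
        """Anchor the frame at the post-void volume centroid and verify by ray
        parity that the origin is strictly inside both surfaces."""
        origin = mesh_centroid(post)
        frame = cls(origin, np.eye(3) if axes is None else axes)
        for name, m in (("pre", pre), ("post", post)):
            if not point_inside(m, origin):
                raise ValueError(
                    f"frame origin {origin} is not inside the {name}-void mesh"
                )
        return frame

    def world_directions(self, theta, phi) -> np.ndarray:
        """Unit vectors in world coordinates for frame angles (theta, phi)."""
        theta = np.atleast_1d(np.asarray(theta, float))
        phi = np.atleast_1d(np.asarray(phi, float))
        local = np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=-1,
        )
        return local @ self.axes

    def local_components(self, world_dirs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(world_dirs) @ self.axes.T

    def angles_of(self, world_dirs: np.ndarray):
        local = self.local_components(world_dirs)
        theta = np.arccos(np.clip(local[:, 2], -1.0, 1.0))
        phi = np.arctan2(local[:, 1], local[:, 0])
        return theta, phi


# ---------------------------------------------------------------------------
# ray-triangle intersection (Moller-Trumbore)
# ---------------------------------------------------------------------------

def ray_triangle_intersect(origin, direction, triangle, eps: float = _EPS):
    """Moller-Trumbore intersection of one ray with one triangle.

    Returns the parametric hit distance ``t >= 0`` (mm, since ``direction``
    is unit) or ``None`` for a miss. Backward intersections (t < 0) are
    misses; degenerate triangles (area < 1e-12 mm^2) are misses with a
    warning.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    v0, v1, v2 = (np.asarray(v, float) for v in triangle)
    e1, e2 = v1 - v0, v2 - v0
    if 0.5 * np.linalg.norm(np.cross(e1, e2)) < 1e-12:
        warnings.warn("degenerate triangle in ray casting; treated as a miss")
        return None
    p = np.cross(direction, e2)
    det = float(e1 @ p)
    if abs(det) < 1e-12:
        return None  # ray parallel to triangle plane
    inv = 1.0 / det
    s = origin - v0
    u = float(s @ p) * inv
    if u < -eps or u > 1.0 + eps:
        return None
    q = np.cross(s, e1)
    v = float(direction @ q) * inv
    if v < -eps or u + v > 1.0 + eps:
        return None
    t = float(e2 @ q) * inv
    return t if t >= -eps else None


def _intersect_all(origin: np.ndarray, direction: np.ndarray, tri: np.ndarray,
                   eps: float = _EPS) -> np.ndarray:
    """Vectorised Moller-Trumbore of one ray against all triangles.

    ``tri`` is (m, 3, 3). Returns the sorted array of forward hit distances.
    """
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    p = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin[None, :] - v0
    u = np.einsum("ij,ij->i", s, p) * inv
    ok &= (u >= -eps) & (u <= 1.0 + eps)
    q = np.cross(s, e1)
    v = (q @ direction) * inv
    ok &= (v >= -eps) & (u + v <= 1.0 + eps)
    t = np.einsum("ij,ij->i", e2, q) * inv
    ok &= t >= -eps
    hits = np.sort(t[ok])
    return np.clip(hits, 0.0, None)


def point_inside(mesh: SurfaceMesh, point) -> bool:
    """Ray-parity inside test (odd number of crossings along +x)."""
    hits = _intersect_all(np.asarray(point, float), np.array([1.0, 0.0, 0.0]),
                          mesh.triangles())
    # collapse numerically coincident hits (shared edges produce duplicates)
    if len(hits) > 1:
        hits = hits[np.concatenate([[True], np.diff(hits) > 1e-9])]
    return len(hits) % 2 == 1


class RadialHit(NamedTuple):
    r: float            # nearest surface distance along the ray (mm)
    multiplicity: int   # number of distinct crossings (1 for star-shaped)


def radial_distance(mesh: SurfaceMesh, frame: SphericalFrame, direction) -> RadialHit:
    """Distance from the frame origin to the surface along (theta, phi).

    ``direction`` is a (theta, phi) pair or a world-space unit vector. For a
    non-star-shaped surface the nearest crossing is returned with the crossing
    count in ``multiplicity``.
    """
    direction = np.asarray(direction, float)
    if direction.shape == (2,):
        d = frame.world_directions(direction[0], direction[1])[0]
    else:
        d = direction / np.linalg.norm(direction)
    hits = _intersect_all(frame.origin, d, mesh.triangles())
    if len(hits) > 1:
        hits = hits[np.concatenate([[True], np.diff(hits) > 1e-9])]
    if len(hits) == 0:
        raise ValueError(
            f"ray from origin along direction {d} does not meet the mesh "
            "(mesh defect or origin outside surface)"
        )
    return RadialHit(float(hits[0]), int(len(hits)))


# ---------------------------------------------------------------------------
# displacement field
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Per-sample total radial displacement d0(theta, phi).

    ``d_theta`` and ``d_phi`` are identically zero: the model admits no
    tangential wall motion. ``d0 = r_pre - r_post`` (positive = inward motion
    during voiding); negative values are retained and flagged.
    """

    theta: np.ndarray
    phi: np.ndarray
    r_pre: np.ndarray
    r_post: np.ndarray
    d0: np.ndarray
    d_theta: np.ndarray
    d_phi: np.ndarray
    multiplicity_pre: np.ndarray
    multiplicity_post: np.ndarray
    n_failed: int
    frame: SphericalFrame
    sampling: str = "pre_vertices"
    region_ap: np.ndarray | None = None   # "anterior" / "posterior"
    region_db: np.ndarray | None = None   # "dome" / "base"
    region_lr: np.ndarray | None = None   # "left" / "right"

    @property
    def n_samples(self) -> int:
        return len(self.d0)

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.d0 < 0))

    def directions_local(self) -> np.ndarray:
        return np.stack(
            [
                np.sin(self.theta) * np.cos(self.phi),
                np.sin(self.theta) * np.sin(self.phi),
                np.cos(self.theta),
            ],
            axis=-1,
        )

    def region_mask(self, name: str) -> np.ndarray:
        if self.region_ap is None:
            raise ValueError("field has no region labels; call partition_regions first")
        table = {
            "anterior": (self.region_ap, "anterior"),
            "posterior": (self.region_ap, "posterior"),
            "dome": (self.region_db, "dome"),
            "base": (self.region_db, "base"),
            "left": (self.region_lr, "left"),
            "right": (self.region_lr, "right"),
        }
        if name not in table:
            raise KeyError(f"unknown region {name!r}")
        arr, value = table[name]
        return arr == value

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "theta_rad": self.theta,
            "phi_rad": self.phi,
            "r_pre_mm": self.r_pre,
            "r_post_mm": self.r_post,
            "d0_mm": self.d0,
        }
        if self.region_ap is not None:
            cols["region_ap"] = self.region_ap
            cols["region_db"] = self.region_db
            cols["region_lr"] = self.region_lr
        return pd.DataFrame(cols)


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)


def compute_displacement_field(
    pre: SurfaceMesh,
    post: SurfaceMesh,
    frame: SphericalFrame,
    sampling="pre_vertices",
    max_fail_fraction: float = 0.05,
) -> DisplacementField:
    """Measure d0(theta, phi) = r_pre - r_post by ray casting.

    ``sampling`` is ``"pre_vertices"`` (one ray per pre-void vertex direction,
    the default) or ``("uniform_sphere", n)`` for mesh-resolution-independent
    statistics. Samples whose ray misses either surface are dropped and
    counted; more than ``max_fail_fraction`` failures raises (the meshes are
    then likely not star-shaped about the chosen origin).
    """
    if sampling == "pre_vertices":
        dirs_world = pre.vertices - frame.origin
        norms = np.linalg.norm(dirs_world, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("a pre-void vertex coincides with the frame origin")
        dirs_world = dirs_world / norms[:, None]
        mode = "pre_vertices"
    else:
        kind, n = sampling
        if kind != "uniform_sphere":
            raise ValueError(f"unknown sampling mode {sampling!r}")
        dirs_world = _fibonacci_directions(int(n)) @ frame.axes
        mode = f"uniform_sphere({int(n)})"

    tri_pre = pre.triangles()
    tri_post = post.triangles()

    r_pre, r_post, mul_pre, mul_post, keep = [], [], [], [], []
    for d in dirs_world:
        hp = _intersect_all(frame.origin, d, tri_pre)
        hq = _intersect_all(frame.origin, d, tri_post)
        if len(hp) == 0 or len(hq) == 0:
            keep.append(False)
            continue
        keep.append(True)
        hp = hp[np.concatenate([[True], np.diff(hp) > 1e-9])] if len(hp) > 1 else hp
        hq = hq[np.concatenate([[True], np.diff(hq) > 1e-9])] if len(hq) > 1 else hq
        r_pre.append(hp[0])
        r_post.append(hq[0])
        mul_pre.append(len(hp))
        mul_post.append(len(hq))

    keep = np.asarray(keep, bool)
    n_failed = int(np.sum(~keep))
    if n_failed > max_fail_fraction * len(dirs_world):
        raise ValueError(
            f"{n_failed}/{len(dirs_world)} radial rays failed; meshes are "
            "likely not star-shaped about the chosen origin"
        )

    theta, phi = frame.angles_of(dirs_world[keep])
    r_pre = np.asarray(r_pre)
    r_post = np.asarray(r_post)
    n = len(r_pre)
    field = DisplacementField(
        theta=theta,
        phi=phi,
        r_pre=r_pre,
        r_post=r_post,
        d0=r_pre - r_post,
        d_theta=np.zeros(n),
        d_phi=np.zeros(n),
        multiplicity_pre=np.asarray(mul_pre, int),
        multiplicity_post=np.asarray(mul_post, int),
        n_failed=n_failed,
        frame=frame,
        sampling=mode,
    )
    return partition_regions(field, frame)


def partition_regions(field: DisplacementField, frame: SphericalFrame) -> DisplacementField:
    """Label every sample with three independent binary regions by the sign of
    its direction components in the frame: anterior (y > 0) / posterior,
    dome (z > 0) / base, left (x > 0) / right. Samples on a boundary plane
    (|component| < 1e-12) go to the positive side (deterministic ties)."""
    local = field.directions_local()
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    field.region_ap = np.where(y >= -_TIE, "anterior", "posterior")
    field.region_db = np.where(z >= -_TIE, "dome", "base")
    field.region_lr = np.where(x >= -_TIE, "left", "right")
    return field


# ---------------------------------------------------------------------------
# regional statistics and asymmetry
# ---------------------------------------------------------------------------

@dataclass
class RegionalStats:
    """Five-number summaries of d0 per region plus the left-right asymmetry
    ratio (%). Quartiles use linear interpolation of the empirical CDF."""

    summaries: dict  # region -> dict(min, q1, median, q3, max)
    asymmetry_ratio: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.summaries).T[["min", "q1", "median", "q3", "max"]]


def fivenum(samples: np.ndarray) -> dict:
    q = np.percentile(np.asarray(samples, float), [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def asymmetry_ratio(median_left: float, median_right: float) -> float:
    """Left-right asymmetry: 100 * |L - R| / mean(L, R).

    Normalising by the mean of the two medians admits values above 100 %
    (severely one-sided wall motion), which an L- or R-only denominator
    would not produce symmetrically.
    """
    if median_left < 0 or median_right < 0:
        raise ValueError("medians must be non-negative")
    mean = 0.5 * (median_left + median_right)
    if mean == 0:
        raise ValueError("asymmetry ratio undefined: both medians are zero")
    return 100.0 * abs(median_left - median_right) / mean


def regional_stats(field: DisplacementField, min_samples: int = 5) -> RegionalStats:
    if field.region_ap is None:
        field = partition_regions(field, field.frame)
    summaries = {}
    for name in REGION_NAMES:
        mask = field.region_mask(name)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"region {name!r} is empty")
        if n < min_samples:
            raise ValueError(f"region {name!r} has only {n} sample(s) (need >= {min_samples})")
        summaries[name] = fivenum(field.d0[mask])
    ar = asymmetry_ratio(summaries["left"]["median"], summaries["right"]["median"])
    return RegionalStats(summaries=summaries, asymmetry_ratio=ar)


# ---------------------------------------------------------------------------
# displacement probability density
# ---------------------------------------------------------------------------

@dataclass
class DensityEstimate:
    """Gaussian-kernel density over d0. ``point_mass`` marks the degenerate
    all-identical-samples case (zero variance)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    point_mass: bool = False
    location: float | None = None

    @property
    def integral(self) -> float:
        if self.point_mass:
            return 1.0
        return float(np.trapezoid(self.density, self.grid))

    @property
    def mode(self) -> float:
        if self.point_mass:
            return float(self.location)
        return float(self.grid[np.argmax(self.density)])


def displacement_density(field_or_samples, bandwidth="auto", n_grid: int = 512) -> DensityEstimate:
    """Gaussian KDE of the displacement distribution (Silverman bandwidth by
    default); the returned density integrates to 1 within 1e-3."""
    samples = (
        field_or_samples.d0
        if isinstance(field_or_samples, DisplacementField)
        else np.asarray(field_or_samples, float)
    )
    if len(samples) < 20:
        raise ValueError("need at least 20 samples for a density estimate")
    if np.ptp(samples) == 0:
        warnings.warn("all displacement samples identical; returning a point mass")
        v = float(samples[0])
        return DensityEstimate(
            grid=np.array([v]), density=np.array([np.inf]), bandwidth=0.0,
            point_mass=True, location=v,
        )
    bw = "silverman" if bandwidth == "auto" else float(bandwidth) / samples.std(ddof=1)
    kde = sp_stats.gaussian_kde(samples, bw_method=bw)
    h = kde.factor * samples.std(ddof=1)
    grid = np.linspace(samples.min() - 5 * h, samples.max() + 5 * h, n_grid)
    return DensityEstimate(grid=grid, density=kde(grid), bandwidth=h)
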