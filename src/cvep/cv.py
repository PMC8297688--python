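"""Conduction-velocity estimation from activation maps.

For every map point: collect the neighbors whose tangent-plane coordinates
fall in a 1 cm x 1 cm patch, fit the activation time with a degree-2
polynomial by least squares, and convert the activation-time gradient to a
velocity with the inverse-gradient rule v = grad T / ||grad T||^2
(gradients in ms/mm invert to speeds in mm/ms = m/s).  Speeds outside the
physiological range [0, 2] m/s are invalidated, not clamped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TissueMesh

#: patch side in tangent-plane coordinates (mm): "1 cm x 1 cm"
PATCH_SIDE = 10.0
#: ball pre-filter radius: half patch diagonal (mm)
PATCH_BALL = 7.1
#: minimum points for a degree-2 fit
MIN_POINTS = 6
#: physiological speed range (m/s)
CV_RANGE = (0.0, 2.0)
#: gradient magnitude below this (ms/mm) marks a flat/collision site
GRAD_FLOOR = 1e-6


@dataclass
class ActivationPointCloud:
    """3D positions (mm) with activation times (ms) and a validity mask."""

    points: np.ndarray
    at: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.at = np.asarray(self.at, dtype=float)
        if self.points.shape[1] == 2:
            self.points = np.column_stack([self.points,
                                           np.zeros(len(self.points))])
        if self.valid is None:
            self.valid = np.isfinite(self.at) & np.isfinite(self.points).all(axis=1)
        if len(self.at) != len(self.points):
            raise ValueError("points and activation times must align")

    @property
    def n(self) -> int:
        return len(self.at)


@dataclass
class CVField:
    """Per-point velocity vectors (m/s) with validity flags and QC stats."""

    points: np.ndarray
    velocity: np.ndarray      # (n, 3) m/s; rows of invalid points are nan
    magnitude: np.ndarray     # (n,) m/s; nan where invalid
    valid: np.ndarray

    @property
    def stats(self) -> dict:
        ok = self.magnitude[self.valid]
        return {
            "n_points": int(len(self.points)),
            "n_valid": int(self.valid.sum()),
            "invalid_fraction": float(1.0 - self.valid.mean()) if len(self.valid) else 1.0,
            "mean_cv": float(ok.mean()) if len(ok) else float("nan"),
            "sd_cv": float(ok.std()) if len(ok) else float("nan"),
        }


def fit_tangent_plane(points: np.ndarray):
    """Total-least-squares plane through a local point set.

    Returns (origin, e1, e2, normal): the centroid, an orthonormal in-plane
    basis, and the unit normal (smallest principal direction).  Raises for
    degenerate (collinear) geometry.
    """
    pts = np.atleast_2d(points)
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    origin = pts.mean(axis=0)
    centered = pts - origin
    # principal axes of the 3x3 scatter
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30):
        raise ValueError("collinear points: tangent plane undefined")
    normal = vt[2] if vt.shape[0] == 3 else np.cross(vt[0], vt[1])
    normal = normal / np.linalg.norm(normal)
    # deterministic in-plane axes: project the global axis least aligned
    # with the normal (keeps patch squares consistently oriented)
    ref = np.eye(3)[int(np.argmin(np.abs(normal)))]
    e1 = ref - (ref @ normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return origin, e1, e2, normal


def extract_patch(cloud: ActivationPointCloud, center_idx: int,
                  tree: cKDTree | None = None):
    """Indices of cloud points inside the 1 cm x 1 cm tangent-plane patch
    centered on point ``center_idx``, plus their in-plane coordinates
    relative to the center.  Returns None if the patch is degenerate."""
    if tree is None:
        tree = cKDTree(cloud.points)
    center = cloud.points[center_idx]
    cand = np.asarray(tree.query_ball_point(center, PATCH_BALL), dtype=int)
    cand = cand[cloud.valid[cand]]
    if len(cand) < 3:
        return None
    try:
        origin, e1, e2, normal = fit_tangent_plane(cloud.points[cand])
    except ValueError:
        return None
    rel = cloud.points[cand] - center
    xy = np.column_stack([rel @ e1, rel @ e2])
    inside = (np.abs(xy[:, 0]) <= PATCH_SIDE / 2) & (np.abs(xy[:, 1]) <= PATCH_SIDE / 2)
    if inside.sum() < MIN_POINTS:
        return None
    return cand[inside], xy[inside], (e1, e2, normal)


def fit_poly2(local_xy: np.ndarray, at: np.ndarray,
              cond_limit: float = 1e8) -> np.ndarray:
    """Least-squares degree-2 coefficients (a0, a1, a2, a3, a4, a5) of
    T(x,y) = a0 + a1 x + a2 y + a3 x^2 + a4 x y + a5 y^2.

    Coordinates are centered/scaled internally for conditioning; the
    returned coefficients are in the original (mm, ms) units.
    """
    xy = np.atleast_2d(local_xy)
    at = np.asarray(at, dtype=float)
    if len(xy) < MIN_POINTS:
        raise ValueError("degree-2 fit needs at least 6 points")
    scale = max(np.abs(xy).max(), 1e-12)
    x, y = xy[:, 0] / scale, xy[:, 1] / scale
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    if np.linalg.cond(design) > cond_limit:
        raise ValueError("rank-deficient design matrix")
    coeff, *_ = np.linalg.lstsq(design, at, rcond=None)
    # undo the scaling
    s = np.array([1.0, scale, scale, scale ** 2, scale ** 2, scale ** 2])
    return coeff / s


def velocity_from_fit(coeffs: np.ndarray) -> np.ndarray:
    """2D velocity (m/s) at the patch center from the inverse-gradient rule.

    grad T = (a1, a2) ms/mm at the center; v = grad T / ||grad T||^2.
    Raises for flat activation (collision/plateau sites).
    """
    g = np.asarray(coeffs, dtype=float)[1:3]
    g2 = g @ g
    if np.sqrt(g2) < GRAD_FLOOR:
        raise ValueError("flat activation: velocity undefined")
    return g / g2


def estimate_cv_field(cloud: ActivationPointCloud) -> CVField:
    """Per-point 3D conduction-velocity vectors for a whole map.

    The 2D in-plane velocity is lifted through the tangent-plane axes;
    points with patches that are too small, rank-deficient fits, flat
    gradients, or speeds outside [0, 2] m/s are marked invalid.
    """
    n = cloud.n
    velocity = np.full((n, 3), np.nan)
    magnitude = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    tree = cKDTree(cloud.points)
    for i in range(n):
        if not cloud.valid[i]:
            continue
        patch = extract_patch(cloud, i, tree)
        if patch is None:
            continue
        idx, xy, (e1, e2, _) = patch
        try:
            coeffs = fit_poly2(xy, cloud.at[idx])
            v2 = velocity_from_fit(coeffs)
        except ValueError:
            continue
        speed = float(np.linalg.norm(v2))
        if not (CV_RANGE[0] <= speed <= CV_RANGE[1]):
            continue
        velocity[i] = v2[0] * e1 + v2[1] * e2
        magnitude[i] = speed
        valid[i] = True
    return CVField(cloud.points.copy(), velocity, magnitude, valid)


def project_to_mesh(cv_field: CVField, mesh: TissueMesh,
                    return_distance: bool = False):
    """Nearest-neighbor projection of valid CV magnitudes onto mesh nodes.

    Ties are broken toward the lowest donor index (cKDTree convention).
    """
    ok = cv_field.valid
    if not ok.any():
        raise ValueError("no valid CV points to project")
    donors = cv_field.points[ok]
    values = cv_field.magnitude[ok]
    tree = cKDTree(donors)
    dist, idx = tree.query(mesh.nodes)
    nodal = values[idx]
    if return_distance:
        return nodal, dist
    return nodal
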