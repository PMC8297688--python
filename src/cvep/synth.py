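"""Synthetic substrates: structured meshes with fiber fields, seeded
conduction-velocity fields with paroxysmal-like or persistent-like
statistics, and eikonal activation maps used as ground truth for the CV
estimator.

The two disease presets encode the printed clinical constraints: the
persistent-like field contains patches of severe slow conduction (below
0.25 m/s) while the paroxysmal-like field has no CV below 0.3 m/s and a
spatial mean 0.40 m/s higher than the persistent one at comparable
standard deviation.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RectBivariateSpline
from scipy.sparse.csgraph import dijkstra

from .cv import ActivationPointCloud
from .mesh import TissueMesh


def gen_sheet_mesh(lx: float, ly: float, h: float,
                   fiber_pattern: str = "uniform",
                   fiber_angle_deg: float = 0.0) -> TissueMesh:
    """Structured quad sheet of lx x ly mm with spacing h.

    ``fiber_pattern``: "uniform" (constant in-plane angle) or "circular"
    (fibers tangent to circles around the sheet center).
    """
    if lx <= 0 or ly <= 0 or h <= 0:
        raise ValueError("dimensions and spacing must be positive")
    nx = int(round(lx / h))
    ny = int(round(ly / h))
    if abs(nx * h - lx) > 1e-6 * h or abs(ny * h - ly) > 1e-6 * h:
        raise ValueError("lx and ly must be multiples of h")
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([gx.ravel(), gy.ravel(),
                             np.zeros((nx + 1) * (ny + 1))])
    # node (i, j) -> j * (nx+1) + i
    i = np.arange(nx)
    j = np.arange(ny)
    ii, jj = np.meshgrid(i, j, indexing="xy")
    n0 = jj * (nx + 1) + ii
    elems = np.column_stack([n0.ravel(), n0.ravel() + 1,
                             n0.ravel() + nx + 2, n0.ravel() + nx + 1])
    elems = np.ascontiguousarray(elems, dtype=np.int64)

    centers = nodes[elems].mean(axis=1)
    if fiber_pattern == "uniform":
        a = np.deg2rad(fiber_angle_deg)
        f0 = np.tile([np.cos(a), np.sin(a), 0.0], (len(elems), 1))
    elif fiber_pattern == "circular":
        rel = centers[:, :2] - np.array([lx / 2, ly / 2])
        r = np.linalg.norm(rel, axis=1)
        r = np.where(r < 1e-9, 1.0, r)
        f0 = np.column_stack([-rel[:, 1] / r, rel[:, 0] / r,
                              np.zeros(len(elems))])
    else:
        raise ValueError(f"unknown fiber pattern {fiber_pattern!r}")
    n0v = np.tile([0.0, 0.0, 1.0], (len(elems), 1))
    s0 = np.cross(n0v, f0)
    grid = {"origin": np.zeros(3), "spacing": np.array([h, h, 1.0]),
            "shape": np.array([nx + 1, ny + 1])}
    return TissueMesh(nodes, elems, f0, s0, n0v, dim=2, grid=grid)


def gen_slab_mesh(lx: float, ly: float, lz: float, h: float,
                  fiber_angle_deg: float = 0.0) -> TissueMesh:
    """Structured hex slab with uniform in-plane fibers."""
    counts = []
    for l in (lx, ly, lz):
        n = int(round(l / h))
        if n < 1 or abs(n * h - l) > 1e-6 * h:
            raise ValueError("dimensions must be positive multiples of h")
        counts.append(n)
    nx, ny, nz = counts
    xs, ys, zs = (np.arange(n + 1) * h for n in counts)
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    nxy = (nx + 1) * (ny + 1)

    def nid(i, j, k):
        return k * nxy + j * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    elems = np.asarray(elems, dtype=np.int64)
    a = np.deg2rad(fiber_angle_deg)
    ne = len(elems)
    f0 = np.tile([np.cos(a), np.sin(a), 0.0], (ne, 1))
    n0v = np.tile([0.0, 0.0, 1.0], (ne, 1))
    s0 = np.cross(n0v, f0)
    return TissueMesh(nodes, elems, f0, s0, n0v, dim=3, grid=None)


@dataclass(frozen=True)
class CVFieldSpec:
    """Statistical description of a synthetic nodal CV field (m/s).

    The smooth Gaussian background has the stated mean/sd and correlation
    length; persistent-like fields add circular slow patches blended down
    to ``patch_floor``.  After patching, the field is re-centered so its
    spatial mean equals ``mean`` exactly (up to clipping), which pins the
    printed 0.40 m/s paroxysmal-persistent mean gap.
    """

    preset: str = "custom"
    mean: float = 0.7
    sd: float = 0.0
    n_patches: int = 0
    patch_radius: float = 6.0    # mm
    patch_floor: float = 0.15    # m/s
    smoothing: float = 8.0       # mm correlation length
    clip_lo: float = 0.05
    clip_hi: float = 2.0
    seed: int = 0

    @classmethod
    def paroxysmal(cls, seed: int = 0) -> "CVFieldSpec":
        return cls(preset="paroxysmal", mean=1.00, sd=0.25, n_patches=0,
                   clip_lo=0.30, seed=seed)

    @classmethod
    def persistent(cls, seed: int = 0) -> "CVFieldSpec":
        return cls(preset="persistent", mean=0.60, sd=0.25, n_patches=3,
                   patch_radius=6.0, patch_floor=0.15, clip_lo=0.05,
                   seed=seed)

    @classmethod
    def uniform(cls, mean: float = 0.7) -> "CVFieldSpec":
        return cls(preset="uniform", mean=mean, sd=0.0)


def cv_field_function(spec: CVFieldSpec, lx: float, ly: float):
    """The continuous CV field for ``spec`` on a [0,lx]x[0,ly] mm domain.

    Returns f(x, y) -> CV in m/s.  The field is a pure function of
    (spec, lx, ly): white noise on a control lattice with spacing equal to
    the smoothing length, interpolated with a bicubic spline (unit variance
    at the control points, correlation length about one spacing), plus
    radial smoothstep slow patches for persistent-like substrates.  The
    spatial mean is pinned to ``spec.mean`` on a fixed evaluation lattice so
    that every mesh sampling the field sees the same function and the
    preset mean gaps are exact by construction.
    """
    if spec.sd == 0.0 and spec.n_patches == 0:
        return lambda x, y: np.full(np.broadcast(x, y).shape, spec.mean)

    rng = np.random.default_rng(spec.seed)
    pad = 2 * spec.smoothing
    xs = np.arange(-pad, lx + pad + spec.smoothing, spec.smoothing)
    ys = np.arange(-pad, ly + pad + spec.smoothing, spec.smoothing)
    noise = rng.standard_normal((len(xs), len(ys)))
    spline = RectBivariateSpline(xs, ys, noise, kx=3, ky=3)
    patches = []
    for _ in range(spec.n_patches):
        margin = spec.patch_radius
        patches.append((rng.uniform(margin, lx - margin),
                        rng.uniform(margin, ly - margin)))

    def blend(cv, x, y):
        """Pull the field down to the patch floor with a radial smoothstep."""
        for cx, cy in patches:
            r = np.hypot(x - cx, y - cy)
            t = np.clip((r - 0.5 * spec.patch_radius)
                        / (0.5 * spec.patch_radius), 0.0, 1.0)
            s = 1.0 - (3.0 * t * t - 2.0 * t * t * t)  # 1 center, 0 outside
            cv = cv + (spec.patch_floor - cv) * s
        return cv

    # pin the spatial mean by shifting the background before patch blending
    # (fixed-point iteration on a fixed evaluation lattice), so patch
    # centers always reach the floor and the mean still lands on spec.mean
    gx, gy = np.meshgrid(np.linspace(0, lx, 201), np.linspace(0, ly, 201),
                         indexing="ij")
    fx, fy = gx.ravel(), gy.ravel()
    bg_lattice = spec.mean + spec.sd * spline(fx, fy, grid=False)
    shift = 0.0
    for _ in range(3):
        shift += spec.mean - blend(bg_lattice + shift, fx, fy).mean()

    def field(x, y):
        bg = spec.mean + spec.sd * spline(x, y, grid=False) + shift
        return np.clip(blend(bg, x, y), spec.clip_lo, spec.clip_hi)

    return field


def gen_cv_field(mesh: TissueMesh, spec: CVFieldSpec) -> np.ndarray:
    """Seed-deterministic nodal CV field (m/s) following ``spec``.

    The underlying continuous field depends only on (spec, domain size), so
    nested mesh refinements sample the same field.
    """
    x = mesh.nodes[:, 0]
    y = mesh.nodes[:, 1]
    f = cv_field_function(spec, float(x.max()), float(y.max()))
    return f(x, y)


def gen_cv_field_at(points: np.ndarray, spec: CVFieldSpec,
                    domain: tuple) -> np.ndarray:
    """Evaluate the same continuous field at arbitrary points (mm)."""
    p = np.atleast_2d(points)
    f = cv_field_function(spec, float(domain[0]), float(domain[1]))
    return f(p[:, 0], p[:, 1])


def eikonal_activation(mesh: TissueMesh, cv_nodal: np.ndarray,
                       source_nodes, spacing: float = 2.5,
                       t0: float = 0.0) -> ActivationPointCloud:
    """Shortest-travel-time activation map for a prescribed CV field.

    Dijkstra on the mesh edge graph (quad edges plus both element diagonals,
    which bounds the metric overestimate); edge travel time is
    length / harmonic-mean of the endpoint CVs.  The map is subsampled to a
    point cloud of roughly ``spacing`` mm to mimic mapping-catheter data.
    Use ``spacing=None`` for all nodes.
    """
    cv = np.asarray(cv_nodal, dtype=float)
    if np.any(cv <= 0):
        raise ValueError("eikonal propagation needs strictly positive CV")
    src = np.atleast_1d(np.asarray(source_nodes, dtype=int))
    if src.size == 0:
        raise ValueError("at least one source node required")

    e = mesh.elems
    pairs = [e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 3]], e[:, [3, 0]],
             e[:, [0, 2]], e[:, [1, 3]]]
    edges = np.unique(np.sort(np.concatenate(pairs), axis=1), axis=0)
    length = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]],
                            axis=1)
    # travel time in ms: mm / (m/s) = mm / (mm/ms)
    tt = length * 0.5 * (1.0 / cv[edges[:, 0]] + 1.0 / cv[edges[:, 1]])
    n = mesh.n_nodes
    g = sp.coo_matrix((tt, (edges[:, 0], edges[:, 1])), shape=(n, n))
    g = g + g.T
    at = dijkstra(g.tocsr(), directed=False, indices=src, min_only=True)
    valid = np.isfinite(at)

    if spacing is None:
        keep = valid
    else:
        stride = max(int(round(spacing / mesh.h)), 1)
        if mesh.grid is None:
            raise ValueError("subsampling requires a structured mesh")
        nx, ny = mesh.grid["shape"]
        ii, jj = np.meshgrid(np.arange(0, nx, stride),
                             np.arange(0, ny, stride), indexing="xy")
        keep = np.zeros(n, dtype=bool)
        keep[jj.ravel() * nx + ii.ravel()] = True
        keep &= valid
    return ActivationPointCloud(points=mesh.nodes[keep], at=at[keep] + t0)


# --- fixture registry ---

@dataclass
class Fixture:
    name: str
    mesh: TissueMesh
    cv: np.ndarray
    spec: CVFieldSpec | None
    checksum: str
    extras: dict


def _checksum(*arrays) -> str:
    hsh = hashlib.sha256()
    for a in arrays:
        hsh.update(np.ascontiguousarray(np.round(np.asarray(a, float), 9)).tobytes())
    return hsh.hexdigest()[:16]


def _fx_cable(seed):
    m = gen_sheet_mesh(40.0, 2.0, 0.25)
    cv = np.full(m.n_nodes, 0.7)
    return m, cv, None, {}


def _fx_uniform(seed):
    m = gen_sheet_mesh(20.0, 20.0, 1.0 / 3.0)
    spec = CVFieldSpec.uniform(0.7)
    return m, gen_cv_field(m, spec), spec, {}


def _fx_parox(seed):
    # fibers along +y: sinus-style pacing from the y=0 edge then propagates
    # mainly along the fiber direction, as physiological activation does
    m = gen_sheet_mesh(50.0, 50.0, 50.0 / 76.0, fiber_angle_deg=90.0)
    spec = CVFieldSpec.paroxysmal(seed)
    return m, gen_cv_field(m, spec), spec, {}


def _fx_persist(seed):
    m = gen_sheet_mesh(50.0, 50.0, 50.0 / 76.0, fiber_angle_deg=90.0)
    spec = CVFieldSpec.persistent(seed)
    return m, gen_cv_field(m, spec), spec, {}


def _fx_spiral(seed):
    """Analytic Archimedean-spiral phase field for singularity detection."""
    m = gen_sheet_mesh(20.0, 20.0, 0.5)
    cv = np.full(m.n_nodes, 0.7)
    x = m.nodes[:, 0] - 10.0
    y = m.nodes[:, 1] - 10.0
    theta = np.arctan2(y, x)
    r = np.hypot(x, y)
    phase = np.mod(theta - 2.0 * np.pi * r / 15.0, 2.0 * np.pi) - np.pi
    return m, cv, None, {"phase": phase, "core": np.array([10.0, 10.0])}


FIXTURES = {
    "cable-1d": _fx_cable,
    "sheet-2x2cm-uniform": _fx_uniform,
    "sheet-5x5cm-paroxysmal": _fx_parox,
    "sheet-5x5cm-persistent": _fx_persist,
    "spiral-phase-field": _fx_spiral,
}


def make_fixture(name: str, seed: int = 1) -> Fixture:
    """Reproducible bundled test cases; unknown names raise with the registry."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; registry: {sorted(FIXTURES)}")
    m, cv, spec, extras = builder(seed)
    return Fixture(name, m, cv, spec, _checksum(m.nodes, cv), extras)
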