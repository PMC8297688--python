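"""Tissue meshes and linear finite-element machinery.

Structured quadrilateral sheets (2D, bilinear elements) and hexahedral slabs
(3D, trilinear elements) with a per-element fiber frame (f0, s0, n0).
Coordinates are in mm throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

_GP = 1.0 / np.sqrt(3.0)


def _quad_shape():
    """Bilinear quad basis at the 2x2 Gauss points.

    Returns (shape (4,4), dshape (4,4,2), weights (4,)) with node order
    (-,-), (+,-), (+,+), (-,+) on the reference square [-1,1]^2.
    """
    signs = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    qp = np.array([[sx * _GP, sy * _GP] for sx, sy in signs])
    n = np.zeros((4, 4))
    dn = np.zeros((4, 4, 2))
    for q, (xi, eta) in enumerate(qp):
        for a, (sx, sy) in enumerate(signs):
            n[q, a] = 0.25 * (1 + sx * xi) * (1 + sy * eta)
            dn[q, a, 0] = 0.25 * sx * (1 + sy * eta)
            dn[q, a, 1] = 0.25 * sy * (1 + sx * xi)
    return n, dn, np.ones(4)


def _hex_shape():
    """Trilinear hex basis at the 2x2x2 Gauss points."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                     dtype=float)
    qp = signs * _GP
    n = np.zeros((8, 8))
    dn = np.zeros((8, 8, 3))
    for q, x in enumerate(qp):
        for a, s in enumerate(signs):
            terms = 1 + s * x
            n[q, a] = 0.125 * terms.prod()
            for d in range(3):
                others = np.prod([terms[e] for e in range(3) if e != d])
                dn[q, a, d] = 0.125 * s[d] * others
    return n, dn, np.ones(8)


@dataclass
class TissueMesh:
    """Conforming structured mesh with per-element fiber frame.

    nodes: (n, 3) mm (2D sheets have z == 0); elems: (ne, 4) quads or
    (ne, 8) hexes; f0/s0/n0: (ne, 3) orthonormal fiber, sheet and normal
    directions.  ``grid`` optionally records structured-grid metadata
    (origin, spacing, node counts per axis) used for fast interpolation.
    """

    nodes: np.ndarray
    elems: np.ndarray
    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    dim: int
    grid: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def h(self) -> float:
        """Characteristic element size: mean longest edge length."""
        first = self.nodes[self.elems[:, 0]]
        second = self.nodes[self.elems[:, 1]]
        return float(np.linalg.norm(second - first, axis=1).mean())

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def validate(self) -> None:
        detjw, _, _, _ = fe_structures(self)
        if detjw.min() <= 0:
            bad = int(np.argmin(detjw.min(axis=1)))
            raise ValueError(f"degenerate element Jacobian in element {bad}")
        for a, b in ((self.f0, self.s0), (self.f0, self.n0), (self.s0, self.n0)):
            if np.abs(np.einsum("ei,ei->e", a, b)).max() > 1e-8:
                raise ValueError("fiber frame not orthonormal")


def fe_structures(mesh: TissueMesh):
    """Per-element quadrature data: (detjw (ne,nq), grad (ne,nq,nn,dim),
    shape (nq,nn), weights (nq,)).  Cached on the mesh instance."""
    hit = getattr(mesh, "_fe_cache", None)
    if hit is not None:
        return hit
    if mesh.elems.shape[1] == 4:
        n, dn, w = _quad_shape()
        coords = mesh.nodes[mesh.elems][:, :, :2]
    else:
        n, dn, w = _hex_shape()
        coords = mesh.nodes[mesh.elems]
    # J[e,q,i,d] = sum_a coords[e,a,i] * dn[q,a,d]
    jac = np.einsum("eai,qad->eqid", coords, dn)
    detj = np.linalg.det(jac)
    invj = np.linalg.inv(jac)
    # physical gradients grad[e,q,a,i] = dn[q,a,d] invj[e,q,d,i]
    grad = np.einsum("qad,eqdi->eqai", dn, invj)
    detjw = detj * w[None, :]
    out = (detjw, grad, n, w)
    mesh._fe_cache = out
    return out


def assemble(mesh: TissueMesh, d_elem: np.ndarray):
    """Galerkin mass and stiffness matrices for linear elements.

    d_elem: per-element diffusion tensor, shape (ne, dim, dim), in mm^2/ms.
    Returns sparse CSR (M, A); A has zero row sums (pure Neumann) and the
    total mass equals the domain area/volume.
    """
    detjw, grad, n, _ = fe_structures(mesh)
    ne, nn = mesh.elems.shape
    d = np.asarray(d_elem)
    if d.shape != (ne, grad.shape[3], grad.shape[3]):
        raise ValueError(f"diffusion tensor shape {d.shape} does not match mesh")
    # local stiffness: K[e,a,b] = sum_q detjw * grad[a] . D grad[b]
    dg = np.einsum("eij,eqbj->eqbi", d, grad)
    k_loc = np.einsum("eqai,eqbi,eq->eab", grad, dg, detjw)
    m_loc = np.einsum("qa,qb,eq->eab", n, n, detjw)
    rows = np.repeat(mesh.elems, nn, axis=1).ravel()
    cols = np.tile(mesh.elems, (1, nn)).ravel()
    nv = mesh.n_nodes
    a_mat = sp.coo_matrix((k_loc.ravel(), (rows, cols)), shape=(nv, nv)).tocsr()
    m_mat = sp.coo_matrix((m_loc.ravel(), (rows, cols)), shape=(nv, nv)).tocsr()
    return m_mat, a_mat


def lumped_mass(mesh: TissueMesh) -> np.ndarray:
    """Row-sum (lumped) nodal volumes."""
    detjw, _, n, _ = fe_structures(mesh)
    loc = np.einsum("qa,eq->ea", n, detjw)
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elems.ravel(), loc.ravel())
    return out


def interpolate_nodal(mesh: TissueMesh, values: np.ndarray,
                      points: np.ndarray) -> np.ndarray:
    """Evaluate a nodal field at arbitrary points with the element basis.

    Requires structured-grid metadata; points outside are clamped to the
    boundary (consistent with evaluating the trace).
    """
    if mesh.grid is None:
        raise ValueError("interpolation requires a structured mesh")
    g = mesh.grid
    origin = np.asarray(g["origin"])
    spacing = np.asarray(g["spacing"])
    shape = np.asarray(g["shape"])  # node counts per axis
    pts = np.atleast_2d(points)[:, : len(shape)]
    loc = (pts - origin[: len(shape)]) / spacing[: len(shape)]
    loc = np.clip(loc, 0, shape - 1 - 1e-12)
    i0 = loc.astype(int)
    f = loc - i0
    if len(shape) == 2:
        nx = shape[0]
        idx = lambda ix, iy: iy * nx + ix  # noqa: E731
        v00 = values[idx(i0[:, 0], i0[:, 1])]
        v10 = values[idx(i0[:, 0] + 1, i0[:, 1])]
        v01 = values[idx(i0[:, 0], i0[:, 1] + 1)]
        v11 = values[idx(i0[:, 0] + 1, i0[:, 1] + 1)]
        fx, fy = f[:, 0], f[:, 1]
        return (v00 * (1 - fx) * (1 - fy) + v10 * fx * (1 - fy)
                + v01 * (1 - fx) * fy + v11 * fx * fy)
    raise NotImplementedError("nodal interpolation implemented for sheets")
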