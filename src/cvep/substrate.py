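"""Conduction-velocity-driven substrate parametrization.

A nodal CV field (m/s) is turned into (a) a heterogeneous anisotropic
diffusivity tensor D = sigma_l f0 x f0 + sigma_t s0 x s0 + sigma_n n0 x n0
per element, and (b) nodal ionic-remodeling fields via the I_CV law.

The conductivity laws:

    sigma_l(x)   = C_l * CV(x)^2
    sigma_t,n(x) = C_l * CV(x)^2   if CV < 0.4 m/s   (isotropic slow zones)
                   C_tn            if CV >= 0.4 m/s

with C_l in seconds, so sigma has units m^2/s (a diffusivity: the membrane
surface-to-volume ratio and capacitance are absorbed into the coefficient).
Both printed coefficient pairs satisfy C_tn = 0.16 * C_l, which makes the
transversal law continuous at the 0.4 m/s threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn import RemodelingLaw, conductance_scales, icv, remodeled_conductances
from .mesh import TissueMesh

#: transversal-conduction threshold (m/s) below which tissue is isotropic
CV_TRANSVERSAL_THRESHOLD = 0.4

#: unit conversion for the solver: 1 m^2/s = 1e3 mm^2/ms
M2_PER_S_TO_MM2_PER_MS = 1.0e3


@dataclass(frozen=True)
class ConductivityCoefficients:
    """Fiber-direction and transversal conductivity constants, in seconds."""

    c_l: float
    c_tn: float
    name: str = "custom"

    def __post_init__(self):
        if self.c_l <= 0 or self.c_tn <= 0:
            raise ValueError("conductivity coefficients must be positive")


PRESETS = {
    "baseline": ConductivityCoefficients(3.0e-4, 0.48e-4, "baseline"),
    "progressed": ConductivityCoefficients(2.0e-4, 0.32e-4, "progressed"),
}


def write_presets(path) -> None:
    """Serialize the shipped coefficient presets (with the I_CV breakpoints
    of the matching remodeling variants) as JSON."""
    import json

    payload = {
        "baseline": {"C_l": 3.0e-4, "C_tn": 0.48e-4, "icv": [0.25, 1.25]},
        "progressed": {"C_l": 2.0e-4, "C_tn": 0.32e-4, "icv": [0.5, 1.25]},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def preset(name: str) -> ConductivityCoefficients:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


def sigma_longitudinal(cv, c_l: float):
    """Fiber-direction diffusivity C_l * CV^2, in m^2/s (cv in m/s)."""
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be nonnegative")
    if c_l <= 0:
        raise ValueError("C_l must be positive")
    out = c_l * cv * cv
    return float(out) if out.ndim == 0 else out


def sigma_transversal(cv, c_l: float, c_tn: float):
    """Transversal/normal diffusivity: follows the longitudinal law below
    0.4 m/s and is the constant C_tn above."""
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be nonnegative")
    out = np.where(cv < CV_TRANSVERSAL_THRESHOLD, c_l * cv * cv, c_tn)
    return float(out) if out.ndim == 0 else out


def build_diffusion_tensor(sigma_l, sigma_t, sigma_n, f0, s0, n0,
                           tol: float = 1e-8) -> np.ndarray:
    """Per-element 3x3 tensor sigma_l f0xf0 + sigma_t s0xs0 + sigma_n n0xn0.

    The frame must be orthonormal to ``tol``; the result is then symmetric
    positive semidefinite with eigenvalues {sigma_l, sigma_t, sigma_n}.
    """
    f0 = np.atleast_2d(f0)
    s0 = np.atleast_2d(s0)
    n0 = np.atleast_2d(n0)
    for v in (f0, s0, n0):
        if np.abs(np.linalg.norm(v, axis=1) - 1.0).max() > tol:
            raise ValueError("fiber frame vectors must be unit length")
    for a, b in ((f0, s0), (f0, n0), (s0, n0)):
        if np.abs(np.einsum("ei,ei->e", a, b)).max() > tol:
            raise ValueError("fiber frame must be orthonormal")
    sl = np.atleast_1d(np.asarray(sigma_l, dtype=float))
    st = np.atleast_1d(np.asarray(sigma_t, dtype=float))
    sn = np.atleast_1d(np.asarray(sigma_n, dtype=float))
    d = (sl[:, None, None] * np.einsum("ei,ej->eij", f0, f0)
         + st[:, None, None] * np.einsum("ei,ej->eij", s0, s0)
         + sn[:, None, None] * np.einsum("ei,ej->eij", n0, n0))
    return d


@dataclass
class SubstrateFields:
    """Everything the solver needs about the tissue.

    Nodal: cv (m/s), icv fraction, remodeled conductances (nS/pF) and the
    dimensionless scale factors the kernels consume.  Per element: the
    sigma triple and the diffusion tensor D (m^2/s, 3x3 symmetric PSD).
    """

    mesh: TissueMesh
    cv_nodal: np.ndarray
    icv_nodal: np.ndarray
    g_to: np.ndarray
    g_cal: np.ndarray
    g_kur: np.ndarray
    scale_to: np.ndarray
    scale_cal: np.ndarray
    scale_kur: np.ndarray
    sigma_l: np.ndarray
    sigma_t: np.ndarray
    sigma_n: np.ndarray
    tensor: np.ndarray
    coefficients: ConductivityCoefficients
    law: RemodelingLaw

    def tensor_mm2_per_ms(self) -> np.ndarray:
        """In-plane (2D) or full (3D) tensor in solver units."""
        d = self.tensor * M2_PER_S_TO_MM2_PER_MS
        if self.mesh.dim == 2:
            return np.ascontiguousarray(d[:, :2, :2])
        return d


def build_substrate(mesh: TissueMesh, cv_nodal: np.ndarray,
                    coefficients: ConductivityCoefficients | str = "baseline",
                    law: RemodelingLaw | None = None) -> SubstrateFields:
    """Apply the sigma and I_CV laws to a nodal CV field.

    Element CV is the arithmetic mean of the element's node values;
    remodeling acts nodewise because the ionic ODEs live on nodes.
    """
    if isinstance(coefficients, str):
        coefficients = preset(coefficients)
    if law is None:
        law = (RemodelingLaw.progressed() if coefficients.name == "progressed"
               else RemodelingLaw.baseline())
    cv_nodal = np.asarray(cv_nodal, dtype=float)
    if cv_nodal.shape != (mesh.n_nodes,):
        raise ValueError("cv must be defined on every mesh node")
    if not np.isfinite(cv_nodal).all():
        raise ValueError("cv field contains non-finite values (fill invalid "
                         "nodes before building the substrate)")
    if mesh.f0 is None:
        raise ValueError("mesh has no fiber field")

    cv_elem = cv_nodal[mesh.elems].mean(axis=1)
    sl = sigma_longitudinal(cv_elem, coefficients.c_l)
    st = sigma_transversal(cv_elem, coefficients.c_l, coefficients.c_tn)
    tensor = build_diffusion_tensor(sl, st, st, mesh.f0, mesh.s0, mesh.n0)

    icv_nodal = icv(cv_nodal, law)
    g_to, g_cal, g_kur = remodeled_conductances(cv_nodal, law)
    s_to, s_cal, s_kur = conductance_scales(cv_nodal, law)
    return SubstrateFields(mesh, cv_nodal, icv_nodal, g_to, g_cal, g_kur,
                           s_to, s_cal, s_kur, sl, st, st.copy(), tensor,
                           coefficients, law)


def uniform_substrate(mesh: TissueMesh, cv: float = 0.7,
                      coefficients="baseline",
                      law: RemodelingLaw | None = None) -> SubstrateFields:
    """Convenience wrapper: spatially uniform prescribed CV."""
    return build_substrate(mesh, np.full(mesh.n_nodes, float(cv)),
                           coefficients, law)
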