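"""Monodomain finite-element solver with segregated ionic coupling.

Space: linear (bi-/tri-linear) elements on quad/hex meshes, homogeneous
Neumann boundary.  Time: BDF of order 1-3 with matching-order extrapolation
of potential and state (startup ramp BDF1 -> 2 -> 3).  The ionic current is
treated with state-variable interpolation (SVI): gates, concentrations and
the extrapolated potential are interpolated to the quadrature points, the
current is evaluated there and tested against the basis functions.

The membrane equation is advanced in physical units (mV, ms) with the
diffusivity in mm^2/ms:

    (alpha/dt M + A) u^{n+1} = (1/dt) M u_BDF - I_ion(u_EXT, w^{n+1}, c^{n+1})
                               + I_app(t^{n+1})
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _crn_kernels as _k
from .crn import IonicState, _vtable, _empty_table
from .mesh import TissueMesh, assemble, fe_structures
from .protocols import Protocol
from .substrate import SubstrateFields

#: normalized-potential affine map: u_norm = (V - V_MIN) / V_SPAN
V_MIN_MV = -84.0
V_SPAN_MV = 100.0

#: structured (line-delimited JSON) progress logs
_LOG = logging.getLogger("cvep.solver")


def bdf_coefficients(order: int):
    """(alpha, history weights, extrapolation weights) for BDF order 1-3.

    The discrete derivative at t^{n+1} is (alpha*u^{n+1} - sum w_k u^{n-k})/dt
    and u_EXT^{n+1} = sum e_k u^{n-k}.
    """
    if order == 1:
        return 1.0, np.array([1.0]), np.array([1.0])
    if order == 2:
        return 1.5, np.array([2.0, -0.5]), np.array([2.0, -1.0])
    if order == 3:
        return 11.0 / 6.0, np.array([3.0, -1.5, 1.0 / 3.0]), np.array([3.0, -3.0, 1.0])
    raise ValueError("BDF order must be in {1, 2, 3}")


@dataclass
class SolverConfig:
    dt: float = 0.05                  # ms
    t_end: float = 200.0              # ms
    bdf_order: int = 3
    linear_solver: str = "direct"     # "direct" | "cg"
    cg_tol: float = 1e-8
    store_stride: float | None = None  # ms between stored frames; None = none
    probe_nodes: tuple = ()           # node ids recorded every step
    use_tables: bool = True
    disable_ionic: bool = False       # pure-diffusion mode for verification
    stop_when_quiescent: bool = False
    quiescent_v: float = -65.0        # mV threshold for early termination
    at_slope_floor_frac: float = 0.1  # validity: fraction of median upstroke
    log_every: int | None = None      # steps between structured log lines

    def __post_init__(self):
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if self.bdf_order not in (1, 2, 3):
            raise ValueError("bdf_order must be 1, 2 or 3")

    def content_hash(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Potential history, on-the-fly activation data and bookkeeping."""

    mesh: TissueMesh
    config: SolverConfig
    times: np.ndarray                 # stored frame times (ms)
    frames: np.ndarray                # (nf, n) potential in mV
    at_time: np.ndarray               # per-node time of max |discrete dV/dt|
    at_slope: np.ndarray              # the max slope itself (mV/ms)
    probe_t: np.ndarray
    probe_v: np.ndarray               # (n_probes, nt)
    state: IonicState                 # final ionic state
    stim_log: list
    config_hash: str
    completed: bool
    t_final: float

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def normalized_frames(self) -> np.ndarray:
        return (self.frames - V_MIN_MV) / V_SPAN_MV


class MonodomainSolver:
    """Assembles once, then advances the coupled system step by step."""

    def __init__(self, mesh: TissueMesh, substrate: SubstrateFields,
                 protocol: Protocol, config: SolverConfig):
        self.mesh = mesh
        self.substrate = substrate
        self.protocol = protocol
        self.config = config
        protocol.validate_support(mesh.nodes)

        d_elem = substrate.tensor_mm2_per_ms()
        self.mass, self.stiff = assemble(mesh, d_elem)
        detjw, _, shape_q, _ = fe_structures(mesh)
        self._detjw = detjw
        self._shape_q = shape_q
        self._tab = _vtable() if config.use_tables else _empty_table()
        self._factors: dict[float, object] = {}

        # constant per-impulse load vectors: M @ (amplitude * indicator)
        self._imp_loads = []
        for imp in protocol.impulses:
            mask = imp.support_mask(mesh.nodes)
            self._imp_loads.append(self.mass @ (mask * imp.amplitude_mv_per_ms))

    # -- linear algebra --
    def _system_solve(self, alpha: float, rhs: np.ndarray) -> np.ndarray:
        key = alpha
        if self.config.linear_solver == "direct":
            fac = self._factors.get(key)
            if fac is None:
                mat = (alpha / self.config.dt) * self.mass + self.stiff
                fac = spla.factorized(mat.tocsc())
                self._factors[key] = fac
            return fac(rhs)
        mat = self._factors.get(key)
        if mat is None:
            mat = ((alpha / self.config.dt) * self.mass + self.stiff).tocsr()
            self._factors[key] = mat
        diag = mat.diagonal()
        out, info = spla.cg(mat, rhs, rtol=self.config.cg_tol,
                            M=sp.diags(1.0 / diag))
        if info != 0:
            res = np.linalg.norm(mat @ out - rhs) / np.linalg.norm(rhs)
            raise RuntimeError(f"CG did not converge (info={info}, rel res {res:.2e})")
        return out

    # -- operations --
    def ionic_step(self, v_ext, w_bdf, w_ext, c_bdf, c_ext, alpha,
                   w_new, c_new) -> None:
        if not (np.isfinite(v_ext).all() and np.isfinite(c_ext).all()):
            bad = (np.argwhere(~np.isfinite(v_ext)) if not np.isfinite(v_ext).all()
                   else np.argwhere(~np.isfinite(c_ext))[:, -1:])
            raise FloatingPointError(
                f"ionic state diverged at node {int(bad[0][-1])}")
        _k.ionic_step(v_ext, w_ext, c_ext, w_bdf, c_bdf,
                      self.substrate.scale_to, self.substrate.scale_cal,
                      self.substrate.scale_kur, self.config.dt, alpha,
                      w_new, c_new, self._tab, self.config.use_tables)
        if not np.isfinite(c_new).all():
            bad = int(np.argwhere(~np.isfinite(c_new))[0][1])
            raise FloatingPointError(f"ionic state diverged at node {bad}")

    def iion_load(self, v_ext, w, c) -> np.ndarray:
        out = np.zeros(self.mesh.n_nodes)
        _k.svi_iion_load(self.mesh.elems, self._shape_q, self._detjw,
                         v_ext, w, c, self.substrate.scale_to,
                         self.substrate.scale_cal, self.substrate.scale_kur,
                         out, self._tab, self.config.use_tables)
        return out

    def applied_load(self, t: float) -> np.ndarray:
        out = np.zeros(self.mesh.n_nodes)
        for imp, load in zip(self.protocol.impulses, self._imp_loads):
            if imp.active(t):
                out += load
        return out

    def potential_step(self, v_bdf, v_ext, w_new, c_new, t_new, alpha):
        dt = self.config.dt
        if self.config.disable_ionic:
            b_ion = 0.0
        else:
            b_ion = self.iion_load(v_ext, w_new, c_new)
        rhs = self.mass @ (v_bdf / dt) - b_ion + self.applied_load(t_new)
        return self._system_solve(alpha, rhs)

    def run(self, initial_state: IonicState | None = None,
            v_init: float | np.ndarray = -81.18) -> SimulationResult:
        cfg = self.config
        n = self.mesh.n_nodes
        nt = int(round(cfg.t_end / cfg.dt))
        state = IonicState.initial(n) if initial_state is None else initial_state.copy()

        v_hist = [np.full(n, v_init, dtype=float) if np.isscalar(v_init)
                  else np.asarray(v_init, dtype=float).copy()]
        w_ring = np.empty((3, 15, n))
        c_ring = np.empty((3, 5, n))
        for s in range(3):
            w_ring[s] = state.gates
            c_ring[s] = state.conc
        slots = [0]  # newest first
        free = [1, 2]

        w_bdf = np.empty((15, n)); w_ext = np.empty((15, n))
        c_bdf = np.empty((5, n)); c_ext = np.empty((5, n))
        w_new = np.empty((15, n)); c_new = np.empty((5, n))

        at_time = np.full(n, np.nan)
        at_slope = np.zeros(n)
        stride = (max(int(round(cfg.store_stride / cfg.dt)), 1)
                  if cfg.store_stride else None)
        frames = []; frame_t = []
        if stride:
            frames.append(v_hist[0].copy()); frame_t.append(0.0)
        probes = list(cfg.probe_nodes)
        probe_v = np.empty((len(probes), nt + 1)) if probes else np.empty((0, 0))
        if probes:
            probe_v[:, 0] = v_hist[0][probes]
        stim_log = []
        active_prev = [False] * len(self.protocol.impulses)
        proto_end = _protocol_end_time(self.protocol)
        completed = True
        t_new = 0.0

        for step in range(nt):
            order = min(cfg.bdf_order, len(v_hist))
            alpha, wts, ext = bdf_coefficients(order)
            v_bdf = sum(w * v_hist[-1 - k] for k, w in enumerate(wts))
            v_ext = sum(w * v_hist[-1 - k] for k, w in enumerate(ext))
            _k.combine_states(w_ring, c_ring,
                              np.asarray(slots[:order], dtype=np.int64),
                              wts, ext, w_bdf, w_ext, c_bdf, c_ext)
            _k.ionic_step(v_ext, w_ext, c_ext, w_bdf, c_bdf,
                          self.substrate.scale_to, self.substrate.scale_cal,
                          self.substrate.scale_kur, cfg.dt, alpha,
                          w_new, c_new, self._tab, cfg.use_tables)
            if step % 200 == 0 and not np.isfinite(c_new[2]).all():
                raise FloatingPointError(
                    f"ionic state diverged near t={(step + 1) * cfg.dt} ms")
            t_new = (step + 1) * cfg.dt
            v_new = self.potential_step(v_bdf, v_ext, w_new, c_new, t_new, alpha)
            if not np.isfinite(v_new).all():
                completed = False
                break

            # activation map on the fly: BDF-form discrete derivative
            slope = np.abs(alpha * v_new - v_bdf) / cfg.dt
            upd = slope > at_slope
            at_time[upd] = t_new
            at_slope[upd] = slope[upd]
            if cfg.log_every and (step + 1) % cfg.log_every == 0:
                _LOG.info(json.dumps({"step": step + 1, "t_ms": t_new,
                                      "max_abs_dvdt": float(slope.max()),
                                      "v_max_mv": float(v_new.max())}))

            # roll histories
            v_hist.append(v_new)
            if len(v_hist) > 3:
                v_hist.pop(0)
            slot = free.pop() if free else slots.pop()
            w_ring[slot] = w_new
            c_ring[slot] = c_new
            slots.insert(0, slot)

            for idx, imp in enumerate(self.protocol.impulses):
                a = imp.active(t_new)
                if a and not active_prev[idx]:
                    stim_log.append((t_new, idx))
                active_prev[idx] = a
            if stride and (step + 1) % stride == 0:
                frames.append(v_new.copy()); frame_t.append(t_new)
            if probes:
                probe_v[:, step + 1] = v_new[probes]
            if (cfg.stop_when_quiescent and step % 50 == 0
                    and t_new > proto_end + 100.0
                    and v_new.max() < cfg.quiescent_v):
                break

        final = IonicState(w_ring[slots[0]].copy(), c_ring[slots[0]].copy())
        return SimulationResult(
            mesh=self.mesh, config=cfg,
            times=np.asarray(frame_t), frames=np.asarray(frames) if frames else np.empty((0, n)),
            at_time=at_time, at_slope=at_slope,
            probe_t=np.arange(nt + 1) * cfg.dt if probes else np.empty(0),
            probe_v=probe_v, state=final, stim_log=stim_log,
            config_hash=self._run_hash(), completed=completed, t_final=t_new)

    def _run_hash(self) -> str:
        hsh = hashlib.sha256()
        hsh.update(self.config.content_hash().encode())
        hsh.update(np.ascontiguousarray(self.mesh.nodes).tobytes())
        hsh.update(np.ascontiguousarray(self.substrate.cv_nodal).tobytes())
        for imp in self.protocol.impulses:
            hsh.update(repr(imp).encode())
        return hsh.hexdigest()[:16]


def _protocol_end_time(protocol: Protocol) -> float:
    end = 0.0
    for imp in protocol.impulses:
        if imp.frequency and imp.n_pulses is None:
            return np.inf
        pulses = imp.n_pulses or 1
        period = 1000.0 / imp.frequency if imp.frequency else 0.0
        end = max(end, imp.delay + (pulses - 1) * period + imp.duration)
    return end


def run(mesh: TissueMesh, substrate: SubstrateFields, protocol: Protocol,
        config: SolverConfig, initial_state: IonicState | None = None,
        v_init=-81.18) -> SimulationResult:
    """Convenience wrapper: build a solver and advance to t_end."""
    return MonodomainSolver(mesh, substrate, protocol, config).run(
        initial_state, v_init)
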