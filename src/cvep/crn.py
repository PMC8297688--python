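"""Courtemanche–Ramirez–Nattel (CRN) human atrial ionic model with
conduction-velocity-dependent electrical remodeling.

The CRN model couples 15 gating variables and 5 ionic concentrations to the
transmembrane potential.  Electrical remodeling in slowly conducting
(fibrotic) tissue is expressed by scaling the maximal conductances of the
transient outward current (I_to), the L-type calcium current (I_CaL) and the
ultrarapid delayed rectifier (I_Kur) with a piecewise-linear function I_CV of
the local conduction velocity: fully remodeled below ``cv_lo``, healthy above
``cv_hi``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _crn_kernels as _k

GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
              "d", "f", "f_ca", "u_g", "v_g", "w_g")
CONC_NAMES = ("na_i", "k_i", "ca_i", "ca_up", "ca_rel")
CURRENT_NAMES = ("i_na", "i_k1", "i_to", "i_kur", "i_kr", "i_ks", "i_cal",
                 "i_nak", "i_naca", "i_bna", "i_bca", "i_pca",
                 "i_up", "i_upleak", "i_tr", "i_rel")

#: published CRN initial conditions (quiescent cell)
V_INIT = -81.18
GATES_INIT = np.array([2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1,
                       4.966e-3, 9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4,
                       9.996e-1, 7.755e-1, 0.0, 1.0, 9.992e-1])
CONC_INIT = np.array([11.17, 139.0, 1.013e-4, 1.488, 1.488])

#: reference maximal conductances subject to remodeling (nS/pF)
GBAR_TO = _k.G_TO
GBAR_CAL = _k.G_CAL
GBAR_KUR = 1.0   # I_Kur conductance is voltage dependent; scale factor only

_VTAB = None


def _vtable():
    global _VTAB
    if _VTAB is None:
        _VTAB = _k.build_vtable()
    return _VTAB


def _empty_table():
    return np.empty((0, _k.TAB_NCOL))


@dataclass
class IonicState:
    """Per-node CRN state: 15 gates in [0,1] and 5 positive concentrations.

    Arrays have shape (15, n) and (5, n); a single cell is n == 1.
    """

    gates: np.ndarray
    conc: np.ndarray

    @classmethod
    def initial(cls, n: int) -> "IonicState":
        return cls(np.repeat(GATES_INIT[:, None], n, axis=1),
                   np.repeat(CONC_INIT[:, None], n, axis=1))

    @property
    def n(self) -> int:
        return self.gates.shape[1]

    def validate(self) -> None:
        if self.gates.shape[0] != 15 or self.conc.shape[0] != 5:
            raise ValueError("expected 15 gates and 5 concentrations")
        if not (np.isfinite(self.gates).all() and np.isfinite(self.conc).all()):
            raise FloatingPointError("non-finite ionic state")
        if self.gates.min() < 0.0 or self.gates.max() > 1.0:
            raise ValueError("gate out of [0, 1]")
        if self.conc.min() <= 0.0:
            raise ValueError("non-positive concentration")

    def copy(self) -> "IonicState":
        return IonicState(self.gates.copy(), self.conc.copy())


@dataclass(frozen=True)
class RemodelingLaw:
    """Piecewise-linear CV -> remodeling fraction I_CV and conductance floors."""

    variant: str = "baseline"
    cv_lo: float = 0.25     # m/s, fully remodeled at or below
    cv_hi: float = 1.25     # m/s, healthy at or above
    floor_to: float = 0.5
    floor_cal: float = 0.3
    floor_kur: float = 0.5

    @classmethod
    def baseline(cls) -> "RemodelingLaw":
        return cls()

    @classmethod
    def progressed(cls) -> "RemodelingLaw":
        """More severe remodeling: fibrotic up to 0.5 m/s."""
        return cls(variant="progressed", cv_lo=0.5)


def icv(cv, law: RemodelingLaw = RemodelingLaw()):
    """Remodeling fraction I_CV in [0,1]: 0 below cv_lo, 1 above cv_hi,
    linear ramp in between.  ``cv`` in m/s, scalar or array."""
    cv_arr = np.asarray(cv, dtype=float)
    if np.any(cv_arr < 0):
        raise ValueError("conduction velocity must be nonnegative")
    frac = (cv_arr - law.cv_lo) / (law.cv_hi - law.cv_lo)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if np.isscalar(cv) or cv_arr.ndim == 0 else out


def remodeled_conductances(cv, law: RemodelingLaw = RemodelingLaw()):
    """(g_to, g_CaL, g_Kur) after CV-dependent remodeling, in nS/pF.

    g_X = (floor_X + I_CV * (1 - floor_X)) * gbar_X.
    """
    f = icv(cv, law)
    g_to = (law.floor_to + f * (1.0 - law.floor_to)) * GBAR_TO
    g_cal = (law.floor_cal + f * (1.0 - law.floor_cal)) * GBAR_CAL
    g_kur = (law.floor_kur + f * (1.0 - law.floor_kur)) * GBAR_KUR
    return g_to, g_cal, g_kur


def conductance_scales(cv, law: RemodelingLaw = RemodelingLaw()):
    """Dimensionless (s_to, s_cal, s_kur) multipliers on the CRN reference
    conductances; this is the form the tissue solver consumes."""
    f = icv(cv, law)
    return (law.floor_to + f * (1.0 - law.floor_to),
            law.floor_cal + f * (1.0 - law.floor_cal),
            law.floor_kur + f * (1.0 - law.floor_kur))


def _scales_arrays(n, scales):
    s_to, s_cal, s_kur = scales
    return (np.full(n, s_to, dtype=float) if np.isscalar(s_to) else np.asarray(s_to, float),
            np.full(n, s_cal, dtype=float) if np.isscalar(s_cal) else np.asarray(s_cal, float),
            np.full(n, s_kur, dtype=float) if np.isscalar(s_kur) else np.asarray(s_kur, float))


def ionic_rhs(v, state: IonicState, scales=(1.0, 1.0, 1.0), use_tables=False):
    """Total ionic current I_ion (pA/pF), gate and concentration derivatives.

    Returns (i_ion, dw, dc, currents) with ``currents`` a dict of the
    per-current breakdown.  ``v`` in mV, scalar or (n,) array matching state.
    """
    v_arr = np.atleast_1d(np.asarray(v, dtype=float))
    if not np.isfinite(v_arr).all():
        raise FloatingPointError("non-finite potential")
    state.validate()
    n = state.n
    s_to, s_cal, s_kur = _scales_arrays(n, scales)
    tab = _vtable() if use_tables else _empty_table()
    cur = np.empty((16, n))
    _k.currents_nodal(v_arr, state.gates, state.conc, s_to, s_cal, s_kur,
                      cur, tab, use_tables)
    dw = np.empty((15, n))
    dc = np.empty((5, n))
    _k.state_rhs(v_arr, state.gates, state.conc, s_to, s_cal, s_kur,
                 dw, dc, tab, use_tables)
    i_ion = cur[:12].sum(axis=0)
    currents = {name: cur[k] for k, name in enumerate(CURRENT_NAMES)}
    return i_ion, dw, dc, currents


@dataclass
class CellTrace:
    """Single-cell pacing result."""

    t: np.ndarray            # ms
    v: np.ndarray            # mV
    apd90: float | None      # ms, last captured beat; None if no AP
    v_rest: float            # diastolic potential before the last beat, mV
    v_peak: float | None
    dvdt_max: float | None   # mV/ms on the last beat upstroke
    captured: bool
    state: IonicState        # final state

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.t, self.v])
        np.savetxt(path, arr, delimiter=",", header="t_ms,V_mV", comments="")


def _bdf_weights(order):
    if order == 1:
        return 1.0, (1.0,), (1.0,)
    if order == 2:
        return 1.5, (2.0, -0.5), (2.0, -1.0)
    if order == 3:
        return 11.0 / 6.0, (3.0, -1.5, 1.0 / 3.0), (3.0, -3.0, 1.0)
    raise ValueError("BDF order must be 1, 2 or 3")


def cell_pace(cycle_length: float = 1000.0, n_beats: int = 4,
              stim_amplitude: float = 20.0, stim_duration: float = 2.0,
              scales=(1.0, 1.0, 1.0), dt: float = 0.02,
              bdf_order: int = 3, state: IonicState | None = None,
              extra_time: float = 0.0, use_tables: bool = True) -> CellTrace:
    """Pace a single CRN cell and report the last-beat APD90.

    ``stim_amplitude`` is in pA/pF (equals mV/ms on the membrane), applied
    for ``stim_duration`` ms at the start of each cycle.  The cell uses the
    same segregated BDF scheme as the tissue solver.  APD90 is measured from
    the time of maximum dV/dt to 90% repolarization toward the preceding
    diastolic potential.
    """
    if cycle_length <= stim_duration:
        raise ValueError("cycle length must exceed stimulus duration")
    state = IonicState.initial(1) if state is None else state.copy()
    s_to, s_cal, s_kur = _scales_arrays(1, scales)
    tab = _vtable() if use_tables else _empty_table()

    t_end = n_beats * cycle_length + extra_time
    nt = int(round(t_end / dt))
    t_out = np.empty(nt + 1)
    v_out = np.empty(nt + 1)
    v_hist = [np.array([V_INIT])]
    w_hist = [state.gates.copy()]
    c_hist = [state.conc.copy()]
    t_out[0] = 0.0
    v_out[0] = V_INIT

    w_new = np.empty_like(state.gates)
    c_new = np.empty_like(state.conc)
    i_ion = np.empty(1)

    for n in range(nt):
        order = min(bdf_order, len(v_hist))
        alpha, wts, ext = _bdf_weights(order)
        v_bdf = sum(wt * v_hist[-1 - k] for k, wt in enumerate(wts))
        v_ext = sum(wt * v_hist[-1 - k] for k, wt in enumerate(ext))
        w_bdf = sum(wt * w_hist[-1 - k] for k, wt in enumerate(wts))
        w_ext = sum(wt * w_hist[-1 - k] for k, wt in enumerate(ext))
        c_bdf = sum(wt * c_hist[-1 - k] for k, wt in enumerate(wts))
        c_ext = sum(wt * c_hist[-1 - k] for k, wt in enumerate(ext))
        c_ext = np.maximum(c_ext, 1e-12)

        _k.ionic_step(v_ext, w_ext, c_ext, w_bdf, c_bdf, s_to, s_cal, s_kur,
                      dt, alpha, w_new, c_new, tab, use_tables)
        t_new = (n + 1) * dt
        phase = t_new % cycle_length
        i_app = stim_amplitude if (phase <= stim_duration and t_new < n_beats * cycle_length) else 0.0
        _k.iion_nodal(v_ext, w_new, c_new, s_to, s_cal, s_kur, i_ion,
                      tab, use_tables)
        v_new = (v_bdf + dt * (-i_ion + i_app)) / alpha

        v_hist.append(v_new)
        w_hist.append(w_new.copy())
        c_hist.append(c_new.copy())
        if len(v_hist) > 3:
            v_hist.pop(0)
            w_hist.pop(0)
            c_hist.pop(0)
        t_out[n + 1] = t_new
        v_out[n + 1] = v_new[0]
        if not np.isfinite(v_new[0]):
            raise FloatingPointError(f"cell integration diverged at t={t_new} ms")

    state = IonicState(w_hist[-1], c_hist[-1])
    apd90, v_rest, v_peak, dvdt_max, captured = _measure_last_beat(
        t_out, v_out, cycle_length, n_beats, stim_duration)
    return CellTrace(t_out, v_out, apd90, v_rest, v_peak, dvdt_max,
                     captured, state)


def _measure_last_beat(t, v, cycle_length, n_beats, stim_duration):
    """APD90 of the last stimulated beat from a (t, v) trace."""
    t0 = (n_beats - 1) * cycle_length
    i0 = np.searchsorted(t, t0)
    v_rest = float(v[max(i0 - 1, 0)])
    seg_t = t[i0:]
    seg_v = v[i0:]
    if len(seg_t) < 3:
        return None, v_rest, None, None, False
    dvdt = np.gradient(seg_v, seg_t)
    iu = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[iu])
    v_peak = float(seg_v.max())
    amplitude = v_peak - v_rest
    # capture requires a genuine regenerative upstroke
    if amplitude < 40.0 or v_peak < -30.0:
        return None, v_rest, v_peak, dvdt_max, False
    v90 = v_peak - 0.9 * amplitude
    below = np.nonzero(seg_v[iu:] <= v90)[0]
    # ignore samples still inside the stimulus artifact
    below = below[seg_t[iu + below] > seg_t[iu] + stim_duration]
    if len(below) == 0:
        return None, v_rest, v_peak, dvdt_max, True
    apd90 = float(seg_t[iu + below[0]] - seg_t[iu])
    return apd90, v_rest, v_peak, dvdt_max, True


def relax_to_rest(t_relax: float = 20000.0, dt: float = 0.05,
                  scales=(1.0, 1.0, 1.0)) -> tuple[float, IonicState]:
    """Resting membrane potential and state after a long quiescent period."""
    tr = cell_pace(cycle_length=t_relax, n_beats=1, stim_amplitude=0.0,
                   stim_duration=1.0, scales=scales, dt=dt)
    return float(tr.v[-1]), tr.state


def parameter_table() -> list[dict]:
    """The CRN parameter set plus the remodeling-law constants, as records
    (name, value, unit, source) suitable for JSON serialization."""
    k = _k
    rows = [
        ("R", k.R_GAS, "J/(mol K)", "CRN"), ("T", k.T_BODY, "K", "CRN"),
        ("F", k.FARADAY, "C/mmol", "CRN"), ("Cm", k.CM, "pF", "CRN"),
        ("V_i", k.V_I, "um^3", "CRN"), ("V_up", k.V_UP, "um^3", "CRN"),
        ("V_rel", k.V_REL, "um^3", "CRN"),
        ("K_o", k.K_O, "mM", "CRN"), ("Na_o", k.NA_O, "mM", "CRN"),
        ("Ca_o", k.CA_O, "mM", "CRN"),
        ("g_Na", k.G_NA, "nS/pF", "CRN"), ("g_K1", k.G_K1, "nS/pF", "CRN"),
        ("g_to", k.G_TO, "nS/pF", "CRN"), ("g_Kr", k.G_KR, "nS/pF", "CRN"),
        ("g_Ks", k.G_KS, "nS/pF", "CRN"), ("g_CaL", k.G_CAL, "nS/pF", "CRN"),
        ("g_bCa", k.G_BCA, "nS/pF", "CRN"), ("g_bNa", k.G_BNA, "nS/pF", "CRN"),
        ("I_NaK_max", k.I_NAK_MAX, "pA/pF", "CRN"),
        ("I_NaCa_max", k.I_NACA_MAX, "pA/pF", "CRN"),
        ("I_pCa_max", k.I_PCA_MAX, "pA/pF", "CRN"),
        ("I_up_max", k.I_UP_MAX, "mM/ms", "CRN"),
        ("K_up", k.K_UP, "mM", "CRN"), ("Ca_up_max", k.CA_UP_MAX, "mM", "CRN"),
        ("k_rel", k.K_REL, "1/ms", "CRN"), ("tau_tr", k.TAU_TR, "ms", "CRN"),
        ("tau_f_Ca", k.TAU_F_CA, "ms", "CRN"), ("tau_u", k.TAU_U, "ms", "CRN"),
        ("K_Q10", k.K_Q10, "", "CRN"),
        ("icv_cv_lo_baseline", 0.25, "m/s", "this-paper"),
        ("icv_cv_lo_progressed", 0.5, "m/s", "this-paper"),
        ("icv_cv_hi", 1.25, "m/s", "this-paper"),
        ("floor_g_to", 0.5, "", "this-paper"),
        ("floor_g_CaL", 0.3, "", "this-paper"),
        ("floor_g_Kur", 0.5, "", "this-paper"),
    ]
    return [{"name": n, "value": v, "unit": u, "source": s}
            for (n, v, u, s) in rows]


def write_parameter_table(path) -> None:
    with open(path, "w") as fh:
        json.dump(parameter_table(), fh, indent=1)
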