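"""Post-processing of monodomain simulations: activation maps, map error
norms, dominant-frequency probes, phase-singularity (rotor) detection and
tracking, anchor/wandering classification, and vulnerable-window scans.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .mesh import TissueMesh, interpolate_nodal
from .solver import SimulationResult

#: phase-map delay (ms) for singularity detection
PHASE_DELAY_MS = 8.0
#: rotor classification thresholds
ANCHOR_RADIUS_MM = 5.0
SUSTAINED_MS = 1000.0
LINE_OF_BLOCK_ASPECT = 3.0


@dataclass
class ActivationMap:
    """Per-node activation times (ms) with a validity mask."""

    at: np.ndarray
    valid: np.ndarray
    mesh: TissueMesh
    window: tuple
    provenance: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def activation_map(result: SimulationResult, window=None,
                   slope_floor_frac: float = 0.1,
                   min_slope: float = 1.0) -> ActivationMap:
    """Activation time = time of maximum |discrete dV/dt| in the window.

    Uses the solver's per-step BDF-form derivative when the window spans the
    whole run; otherwise recomputes from stored frames (stride must be at
    most 1 ms).  Nodes whose maximum slope is below ``slope_floor_frac`` of
    the global median upstroke slope, or below the absolute floor
    ``min_slope`` (mV/ms; genuine upstrokes exceed 50 mV/ms), never
    depolarized and are invalid.
    """
    if window is None:
        window = (0.0, result.t_final)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")

    full_run = t0 <= 0.0 and t1 >= result.t_final - 1e-9
    if full_run:
        at = result.at_time.copy()
        slope = result.at_slope.copy()
    else:
        if result.frames.shape[0] < 3:
            raise ValueError("windowed activation map needs stored frames")
        stride = np.diff(result.times).min()
        if stride > 1.0 + 1e-9:
            raise ValueError("history stride too coarse (need <= 1 ms)")
        sel = (result.times >= t0) & (result.times <= t1)
        times = result.times[sel]
        frames = result.frames[sel]
        # BDF1-form discrete derivative on the stored stride
        dv = np.abs(np.diff(frames, axis=0)) / np.diff(times)[:, None]
        imax = np.argmax(dv, axis=0)  # argmax -> earliest index on ties
        at = times[imax + 1]
        slope = dv[imax, np.arange(dv.shape[1])]

    med = np.median(slope)
    valid = (np.isfinite(at) & (slope >= slope_floor_frac * med)
             & (slope >= min_slope))
    at = np.where(valid, at, np.nan)
    return ActivationMap(at, valid, result.mesh, (t0, t1),
                         provenance=result.config_hash)


def relative_error(map_coarse: ActivationMap, map_ref: ActivationMap) -> float:
    """Norm-1 relative activation-map error on the reference nodes.

    The coarse map is interpolated to the reference nodes with the element
    basis; err = sum|AT - AT_ref| / sum|AT_ref| over nodes valid in both.
    """
    at_i = interpolate_nodal(map_coarse.mesh,
                             np.where(map_coarse.valid, map_coarse.at, np.nan),
                             map_ref.mesh.nodes)
    ok = map_ref.valid & np.isfinite(at_i)
    if not ok.any():
        raise ValueError("no commonly valid nodes between the two maps")
    ref = map_ref.at[ok]
    return float(np.abs(at_i[ok] - ref).sum() / np.abs(ref).sum())


def dominant_frequency(result: SimulationResult, probe_nodes=None,
                       min_duration_ms: float = 2000.0,
                       resolution_hz: float = 0.25) -> np.ndarray:
    """Spectral peak (Hz) of the detrended potential at probe nodes.

    Probes default to the nodes recorded during the run.  Requires at least
    ``min_duration_ms`` of history; silent traces return nan.
    """
    if probe_nodes is None:
        if result.probe_v.size == 0:
            raise ValueError("no probe traces recorded")
        traces = result.probe_v
        dt = result.probe_t[1] - result.probe_t[0]
    else:
        if result.frames.shape[0] < 3:
            raise ValueError("need stored frames to probe arbitrary nodes")
        traces = result.frames[:, probe_nodes].T
        dt = float(np.diff(result.times).mean())
    if traces.shape[1] * dt < min_duration_ms:
        raise ValueError(f"need >= {min_duration_ms} ms of history")

    fs = 1000.0 / dt  # Hz
    nfft = int(2 ** np.ceil(np.log2(fs / resolution_hz)))
    nfft = max(nfft, traces.shape[1])
    out = np.empty(traces.shape[0])
    for i, tr in enumerate(traces):
        x = detrend(tr)
        if np.ptp(x) < 1.0:  # < 1 mV of activity: silent
            out[i] = np.nan
            continue
        spec = np.abs(np.fft.rfft(x * np.hanning(len(x)), n=nfft))
        freqs = np.fft.rfftfreq(nfft, d=dt / 1000.0)
        band = (freqs > 0.5) & (freqs < 30.0)
        out[i] = freqs[band][np.argmax(spec[band])]
    return out


def phase_field(result: SimulationResult, t: float,
                tau: float = PHASE_DELAY_MS) -> np.ndarray:
    """Nodal activation phase at time t from the delay-embedding
    phi = atan2(u(t - tau) - u_mean, u(t) - u_mean)."""
    times = result.times
    if times.size < 3:
        raise ValueError("phase analysis needs stored frames")
    i_now = int(np.argmin(np.abs(times - t)))
    i_del = int(np.argmin(np.abs(times - (t - tau))))
    if times[0] > t - tau or i_del == i_now:
        raise ValueError("insufficient history for the phase delay")
    u_mean = result.frames.mean(axis=0)
    return np.arctan2(result.frames[i_del] - u_mean,
                      result.frames[i_now] - u_mean)


def _winding(phase: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Discrete phase winding around every element (multiples of 2*pi)."""
    ph = phase[elems]  # (ne, 4)
    d = np.diff(np.concatenate([ph, ph[:, :1]], axis=1), axis=1)
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    return d.sum(axis=1) / (2.0 * np.pi)


def phase_singularities(result: SimulationResult, t: float,
                        tau: float = PHASE_DELAY_MS):
    """Phase singularities at time t: (positions (k,3) mm, chirality (k,)).

    A singularity sits in any element whose corner phases wind by +-2*pi.
    """
    phase = phase_field(result, t, tau)
    return phase_singularities_from_phase(result.mesh, phase)


def phase_singularities_from_phase(mesh: TissueMesh, phase: np.ndarray):
    wind = _winding(phase, mesh.elems)
    hit = np.abs(wind) > 0.5
    centers = mesh.nodes[mesh.elems[hit]].mean(axis=1)
    chirality = np.sign(wind[hit]).astype(int)
    return centers, chirality


@dataclass
class RotorTrack:
    """Time-stamped trajectory of one phase singularity."""

    t: np.ndarray          # ms
    positions: np.ndarray  # (k, 3) mm
    chirality: int

    @property
    def lifetime(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def bounding_radius(self) -> float:
        c = self.positions.mean(axis=0)
        return float(np.linalg.norm(self.positions - c, axis=1).max())

    @property
    def aspect_ratio(self) -> float:
        """Elongation of the trajectory cloud (functional lines of block
        show up as elongated tip paths)."""
        if len(self.positions) < 3:
            return 1.0
        c = self.positions - self.positions.mean(axis=0)
        svals = np.linalg.svd(c[:, :2], compute_uv=False)
        if svals[1] < 1e-9:
            return np.inf
        return float(svals[0] / svals[1])


def track_singularities(result: SimulationResult, t_start: float,
                        t_end: float, stride_ms: float = 2.0,
                        tau: float = PHASE_DELAY_MS,
                        link_radius_mm: float = 6.0) -> list:
    """Greedy nearest-neighbor linking of per-frame singularities into
    RotorTracks (same chirality, jump <= link_radius per frame)."""
    ts = np.arange(t_start, t_end + 1e-9, stride_ms)
    open_tracks: list[dict] = []
    done: list[RotorTrack] = []
    for t in ts:
        try:
            pos, chi = phase_singularities(result, t, tau)
        except ValueError:
            continue
        used = np.zeros(len(pos), dtype=bool)
        still_open = []
        for tr in open_tracks:
            best, bd = -1, link_radius_mm
            for i in range(len(pos)):
                if used[i] or chi[i] != tr["chi"]:
                    continue
                d = np.linalg.norm(pos[i] - tr["pos"][-1])
                if d <= bd:
                    best, bd = i, d
            if best >= 0:
                used[best] = True
                tr["t"].append(t)
                tr["pos"].append(pos[best])
                still_open.append(tr)
            else:
                done.append(RotorTrack(np.array(tr["t"]),
                                       np.array(tr["pos"]), tr["chi"]))
        open_tracks = still_open
        for i in range(len(pos)):
            if not used[i]:
                open_tracks.append({"t": [t], "pos": [pos[i]],
                                    "chi": int(chi[i])})
    for tr in open_tracks:
        done.append(RotorTrack(np.array(tr["t"]), np.array(tr["pos"]),
                               tr["chi"]))
    return done


def classify_rotor(track: RotorTrack, cv_nodal=None, mesh=None,
                   anchor_radius: float = ANCHOR_RADIUS_MM,
                   sustained_ms: float = SUSTAINED_MS):
    """(label, info): 'anchored' for a compact long-lived tip, 'wandering'
    for a drifting long-lived tip, 'terminated' otherwise.  If a CV field is
    supplied, reports the mean CV near the trajectory."""
    info = {"lifetime_ms": track.lifetime,
            "bounding_radius_mm": track.bounding_radius,
            "aspect_ratio": track.aspect_ratio,
            "line_of_block": bool(track.aspect_ratio > LINE_OF_BLOCK_ASPECT)}
    if cv_nodal is not None and mesh is not None and len(track.positions):
        c = track.positions.mean(axis=0)
        r = max(track.bounding_radius, 2.0)
        near = np.linalg.norm(mesh.nodes - c, axis=1) <= r
        info["mean_cv_near_track"] = float(cv_nodal[near].mean()) if near.any() else np.nan
    if track.lifetime > sustained_ms:
        label = "anchored" if track.bounding_radius < anchor_radius else "wandering"
    else:
        label = "terminated"
    return label, info


def classify_s1s2_outcome(result: SimulationResult, ci: float,
                          s2_center, stride_ms: float = 2.0,
                          rotation_period_ms: float = 150.0,
                          propagation_radius_mm: float = 12.0) -> str:
    """Outcome of one S1-S2 run: 'early' (S2 blocked), 'reentry'
    (singularities persisting beyond two rotation periods after S2), or
    'late' (a single propagated extra beat that extinguishes)."""
    # did S2 elicit a propagated wave? look for depolarization beyond
    # propagation_radius of the S2 site after the S2 time
    sel = result.times > ci + 10.0
    if not sel.any():
        raise ValueError("simulation too short for the coupling interval")
    dist = np.linalg.norm(result.mesh.nodes - np.asarray(s2_center), axis=1)
    far = dist > propagation_radius_mm
    repol_before = result.frames[result.times <= ci][-1][far]
    after = result.frames[sel][:, far]
    newly_depol = ((after > -40.0) & (repol_before < -60.0)[None, :]).any()

    t_hist0 = result.times[0]
    t0 = max(ci + 2 * PHASE_DELAY_MS, t_hist0 + PHASE_DELAY_MS + stride_ms)
    tracks = track_singularities(result, t0, result.t_final, stride_ms)
    longest = max((tr.lifetime for tr in tracks), default=0.0)
    if longest > 2.0 * rotation_period_ms:
        return "reentry"
    return "late" if newly_depol else "early"


def vulnerable_window_scan(protocols_list, run_fn, s2_center,
                           **classify_kw):
    """Classify every S1-S2 protocol and report the reentry window.

    run_fn(protocol) -> SimulationResult.  Returns (window bounds or None,
    {CI: outcome}).  A non-contiguous reentry range is reported as the
    enclosing bounds with a warning flag in the outcome dict.
    """
    outcomes = {}
    for proto in protocols_list:
        ci = proto.impulses[-1].delay
        res = run_fn(proto)
        outcomes[ci] = classify_s1s2_outcome(res, ci, s2_center,
                                             **classify_kw)
    cis = sorted(outcomes)
    reentry = [ci for ci in cis if outcomes[ci] == "reentry"]
    if not reentry:
        return None, outcomes
    lo, hi = min(reentry), max(reentry)
    contiguous = all(outcomes[ci] == "reentry"
                     for ci in cis if lo <= ci <= hi)
    if not contiguous:
        outcomes["warning"] = "non-contiguous reentry range"
    return (lo, hi), outcomes


def window_width(bounds, cis) -> float:
    """Width of a vulnerable window in ms, counting grid resolution: a
    single reentrant CI on a grid of spacing d contributes d."""
    if bounds is None:
        return 0.0
    cis = sorted(c for c in cis if isinstance(c, (int, float)))
    d = min(np.diff(cis)) if len(cis) > 1 else 1.0
    return float(bounds[1] - bounds[0] + d)
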