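"""Canned study experiments built from the library modules.

These functions define the package's standard numerical experiments at
configurable problem sizes: the space-time refinement ladder for the
activation map, planar-wave speed calibration, trigger-dominance runs,
synthetic-preset statistics, CV-estimator round-trips and S1-S2
vulnerable-window scans.
"""
from __future__ import annotations

import numpy as np

from . import analysis, cv as cvmod, protocols, solver, substrate, synth
from .crn import RemodelingLaw


def sinus_protocol(mesh, paroxysmal: bool = True) -> protocols.Protocol:
    """Single sinus-rhythm-style activation: the three delayed spherical
    impulses of the baseline preset, one cycle."""
    base = protocols.baseline_preset(mesh=mesh, paroxysmal=paroxysmal)
    imps = [protocols.Impulse(i.shape, i.center, i.size, i.amplitude,
                              i.duration, i.frequency, i.delay, n_pulses=1)
            for i in base.impulses]
    return protocols.Protocol(imps, name="sinus")


def refinement_ladder(side_mm: float = 50.0, base_divisions: int = 76,
                      window_ms: float = 200.0, seed: int = 1,
                      ladder=((1, 0.1), (1, 0.05), (2, 0.1), (2, 0.05)),
                      reference=(4, 0.025), preset: str = "baseline"):
    """Activation-map errors of a space-time refinement ladder.

    Runs a sinus-rhythm activation of the paroxysmal-like synthetic
    substrate at each (refinement factor, dt) pair and at the reference
    pair, and returns {(h_mm, dt): err} against the reference map plus the
    reference (h, dt).  Refinement factors are relative to
    side_mm/base_divisions so grids are exactly nested.
    """
    spec = synth.CVFieldSpec.paroxysmal(seed)
    results = {}

    def one(factor, dt):
        h = side_mm / (base_divisions * factor)
        m = synth.gen_sheet_mesh(side_mm, side_mm, h, fiber_angle_deg=90.0)
        cvf = synth.gen_cv_field(m, spec)
        sub = substrate.build_substrate(m, cvf, preset)
        proto = sinus_protocol(m)
        cfg = solver.SolverConfig(dt=dt, t_end=window_ms)
        res = solver.run(m, sub, proto, cfg)
        return analysis.activation_map(res), h

    ref_map, h_ref = one(*reference)
    errors = {}
    for factor, dt in ladder:
        amap, h = one(factor, dt)
        errors[(round(h, 4), dt)] = analysis.relative_error(amap, ref_map)
    return errors, (round(h_ref, 4), reference[1])


def speed_calibration(cv_targets=(0.4, 0.7, 1.0), h: float = 1.0 / 3.0,
                      c_l: float = 3.0e-4, dt: float = 0.05,
                      length_mm: float = 40.0):
    """Measured planar-wave speed on a thin cable for prescribed CVs.

    Returns {cv_target: measured speed (m/s)}; speed is the inverse slope
    of the activation-time regression along the cable, away from the ends.
    """
    width = max(2 * h, 2.0)
    width = round(width / h) * h
    coeff = substrate.ConductivityCoefficients(c_l, 0.16 * c_l, "calib")
    out = {}
    for cv in cv_targets:
        m = synth.gen_sheet_mesh(length_mm, width, h)
        sub = substrate.build_substrate(m, np.full(m.n_nodes, cv), coeff,
                                        law=RemodelingLaw.baseline())
        s1 = protocols.Protocol([protocols.Impulse(
            "slab", (1.0, 0.0, 0.0), 2.0, 200.0, 5.0, None, 0.0, n_pulses=1)])
        t_need = length_mm / cv * 1.6 + 20.0
        cfg = solver.SolverConfig(dt=dt, t_end=t_need)
        res = solver.run(m, sub, s1, cfg)
        amap = analysis.activation_map(res)
        x = m.nodes[:, 0]
        sel = (x > 0.25 * length_mm) & (x < 0.85 * length_mm) & amap.valid
        slope = np.polyfit(x[sel], amap.at[sel], 1)[0]  # ms/mm
        out[cv] = 1.0 / slope  # mm/ms = m/s
    return out


def trigger_dominance(side_mm: float = 50.0, divisions: int = 76,
                      cv: float = 0.7, t_end_ms: float = 2500.0,
                      dt: float = 0.1, preset: str = "baseline"):
    """Baseline (1.82 Hz) + corner trigger (8.26 Hz) on a uniform sheet;
    returns (dominant frequency at a probe >= 3 cm from the trigger,
    probe distance mm, result)."""
    m = synth.gen_sheet_mesh(side_mm, side_mm, side_mm / divisions)
    sub = substrate.build_substrate(m, np.full(m.n_nodes, cv), preset)
    proto = protocols.combined_preset(m)
    trig = np.asarray(protocols.default_trigger_site(m))
    dist = np.linalg.norm(m.nodes - trig, axis=1)
    want = np.argsort(np.abs(dist - max(30.0, dist.max() - 5.0)))[0]
    probe = int(want)
    cfg = solver.SolverConfig(dt=dt, t_end=t_end_ms, probe_nodes=(probe,))
    res = solver.run(m, sub, proto, cfg)
    df = analysis.dominant_frequency(res)[0]
    return df, float(dist[probe]), res


def preset_statistics(side_mm: float = 50.0, divisions: int = 76,
                      seeds=(1, 2, 3, 4, 5)):
    """Mean-CV gap (m/s) and sd ratio between the paroxysmal-like and
    persistent-like presets over matched seeds."""
    gaps, sd_ratios = [], []
    m = synth.gen_sheet_mesh(side_mm, side_mm, side_mm / divisions)
    for seed in seeds:
        cv_par = synth.gen_cv_field(m, synth.CVFieldSpec.paroxysmal(seed))
        cv_per = synth.gen_cv_field(m, synth.CVFieldSpec.persistent(seed))
        gaps.append(cv_par.mean() - cv_per.mean())
        sd_ratios.append(cv_par.std() / cv_per.std())
    return float(np.mean(gaps)), float(np.mean(sd_ratios)), gaps, sd_ratios


def cv_roundtrip(side_mm: float = 50.0, h: float = 1.0, seed: int = 3,
                 spacing: float = 2.5):
    """Median relative error of the CV estimator on an eikonal activation
    map of a smooth synthetic field in [0.3, 1.2] m/s."""
    m = synth.gen_sheet_mesh(side_mm, side_mm, h)
    spec = synth.CVFieldSpec(preset="custom", mean=0.75, sd=0.15,
                             smoothing=10.0, clip_lo=0.3, clip_hi=1.2,
                             seed=seed)
    cvf = synth.gen_cv_field(m, spec)
    src = int(np.argmin(np.linalg.norm(m.nodes - m.nodes.mean(0), axis=1)))
    cloud = synth.eikonal_activation(m, cvf, [src], spacing=spacing)
    est = cvmod.estimate_cv_field(cloud)
    # compare against the true field at the cloud points, away from the source
    truth = synth.gen_cv_field_at(cloud.points, spec, (side_mm, side_mm))
    d = np.linalg.norm(cloud.points - m.nodes[src], axis=1)
    ok = est.valid & (d > 7.5)
    rel = np.abs(est.magnitude[ok] - truth[ok]) / truth[ok]
    return float(np.median(rel)), est, cvf


def s1s2_scan(coupling_intervals, preset: str = "baseline",
              cv: float = 0.25, side_mm: float = 45.0, h: float = 0.75,
              dt: float = 0.1, law: RemodelingLaw | None = None,
              t_after_s2_ms: float = 700.0, s2_radius: float = 8.0):
    """Pinwheel (S1-S2) vulnerable-window scan on a uniform slow sheet.

    S1 is a planar wave from the left edge; S2 a disc at the sheet center
    delivered at each coupling interval.  Returns (window bounds or None,
    {CI: outcome}).
    """
    m = synth.gen_sheet_mesh(side_mm, side_mm, h)
    law = law or RemodelingLaw.progressed()
    sub = substrate.build_substrate(m, np.full(m.n_nodes, cv), preset, law)
    center = (side_mm / 2, side_mm / 2, 0.0)
    protos = protocols.s1s2_preset((1.0, 0.0, 0.0), center,
                                   list(coupling_intervals),
                                   s2_size=s2_radius)

    def run_one(proto):
        ci = proto.impulses[-1].delay
        cfg = solver.SolverConfig(dt=dt, t_end=ci + t_after_s2_ms,
                                  store_stride=2.0,
                                  stop_when_quiescent=True)
        return solver.run(m, sub, proto, cfg)

    return analysis.vulnerable_window_scan(protos, run_one, center)
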