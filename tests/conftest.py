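"""Shared fixtures: small meshes, a relaxed resting cell state, and one
reference cable simulation reused by several analysis tests."""
from __future__ import annotations

import pytest

from cvep import crn, protocols, solver, substrate, synth


@pytest.fixture(scope="session")
def small_sheet():
    """2 x 2 cm sheet at 0.5 mm spacing with uniform fibers."""
    return synth.gen_sheet_mesh(20.0, 20.0, 0.5)


@pytest.fixture(scope="session")
def rest_state():
    """CRN state relaxed for 5 s of quiescence (near-equilibrium)."""
    tr = crn.cell_pace(cycle_length=5000.0, n_beats=1, stim_amplitude=0.0,
                       stim_duration=1.0, dt=0.05)
    return float(tr.v[-1]), tr.state


@pytest.fixture(scope="session")
def cable_run():
    """Planar wave on a thin cable (prescribed CV 0.7 m/s, h = 1/3 mm)."""
    m = synth.gen_sheet_mesh(40.0, 2.0, 1.0 / 3.0)
    sub = substrate.uniform_substrate(m, 0.7, "baseline")
    proto = protocols.Protocol([protocols.Impulse(
        "slab", (1.0, 0.0, 0.0), 2.0, 200.0, 5.0, None, 0.0, n_pulses=1)])
    cfg = solver.SolverConfig(dt=0.05, t_end=90.0, store_stride=1.0)
    res = solver.run(m, sub, proto, cfg)
    return m, sub, res
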