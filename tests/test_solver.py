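"""Monodomain solver: assembly oracles, BDF scheme, conservation,
propagation physics and determinism."""
import numpy as np
import pytest

from cvep import crn, protocols, solver, substrate, synth
from cvep.mesh import assemble, lumped_mass
from cvep.solver import SolverConfig, bdf_coefficients


class TestAssembly:
    def test_stiffness_kernel_contains_constants(self, small_sheet):
        ne = small_sheet.n_elems
        d = np.tile(np.eye(2) * 0.1, (ne, 1, 1))
        _, a = assemble(small_sheet, d)
        ones = np.ones(small_sheet.n_nodes)
        norm_a = np.abs(a.data).max()
        assert np.abs(a @ ones).max() < 1e-10 * norm_a

    def test_unit_square_element_matches_hand_integration(self):
        m = synth.gen_sheet_mesh(1.0, 1.0, 1.0)
        sigma = 0.7
        _, a = assemble(m, np.array([sigma * np.eye(2)]))
        # bilinear-element stiffness on the unit square, local node order
        k_local = (sigma / 6.0) * np.array([[4, -1, -2, -1],
                                            [-1, 4, -1, -2],
                                            [-2, -1, 4, -1],
                                            [-1, -2, -1, 4]])
        perm = m.elems[0]  # local -> global
        a_local = a.toarray()[np.ix_(perm, perm)]
        assert np.allclose(a_local, k_local, atol=1e-12)

    def test_total_mass_equals_area(self, small_sheet):
        d = np.tile(np.eye(2), (small_sheet.n_elems, 1, 1))
        mass, _ = assemble(small_sheet, d)
        assert mass.sum() == pytest.approx(400.0, rel=1e-10)
        assert lumped_mass(small_sheet).sum() == pytest.approx(400.0, rel=1e-10)
        # row sums equal nodal lumped volumes
        np.testing.assert_allclose(np.asarray(mass.sum(axis=1)).ravel(),
                                   lumped_mass(small_sheet), rtol=1e-10)

    def test_symmetry(self, small_sheet):
        d = np.tile(np.diag([0.3, 0.05]), (small_sheet.n_elems, 1, 1))
        mass, a = assemble(small_sheet, d)
        assert (a - a.T).count_nonzero() == 0 or \
            np.abs((a - a.T).data).max() < 1e-12
        assert np.abs((mass - mass.T).data).max() < 1e-14 if (mass - mass.T).nnz else True

    def test_hex_slab_mass_equals_volume(self):
        m = synth.gen_slab_mesh(6.0, 4.0, 2.0, 1.0)
        d = np.tile(np.eye(3), (m.n_elems, 1, 1))
        mass, a = assemble(m, d)
        assert mass.sum() == pytest.approx(48.0, rel=1e-10)
        assert np.abs(a @ np.ones(m.n_nodes)).max() < 1e-10

    def test_degenerate_element_detected(self):
        m = synth.gen_sheet_mesh(2.0, 2.0, 1.0)
        m.nodes[0] = m.nodes[4]  # collapse one corner
        with pytest.raises(ValueError, match="element"):
            m.validate()


class TestBDF:
    def test_coefficients_order1(self):
        a, w, e = bdf_coefficients(1)
        assert a == 1.0 and tuple(w) == (1.0,) and tuple(e) == (1.0,)

    def test_coefficients_order2_taylor_oracle(self):
        a, w, e = bdf_coefficients(2)
        assert a == 1.5 and tuple(w) == (2.0, -0.5)
        assert tuple(e) == (2.0, -1.0)
        # consistency on polynomials: derivative of t^2 at t=2h is 4h
        h = 0.1
        vals = np.array([(2 * h) ** 2, h ** 2, 0.0])  # u(t_{n+1}), u(t_n)...
        deriv = (a * vals[0] - (w[0] * vals[1] + w[1] * vals[2])) / h
        assert deriv == pytest.approx(2 * (2 * h))

    def test_order3_consistency_on_cubic(self):
        a, w, e = bdf_coefficients(3)
        h = 0.05
        t = np.array([3, 2, 1, 0.0]) * h
        u = t ** 3
        deriv = (a * u[0] - (w * u[1:]).sum()) / h
        assert deriv == pytest.approx(3 * (3 * h) ** 2, rel=1e-10)
        # extrapolation exact for quadratics
        uq = t ** 2
        assert (e * uq[1:]).sum() == pytest.approx(uq[0], rel=1e-10)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_observed_convergence_order_on_scalar_ode(self, order):
        """du/dt = lam*u integrated with the BDF scheme; Richardson triplet."""
        lam = -1.0

        def integrate(dt, t_end=1.0):
            n = int(round(t_end / dt))
            # seed the multistep history with exact values so the startup
            # ramp does not mask the asymptotic order
            hist = [np.exp(lam * k * dt) for k in range(order)]
            a, w, _ = bdf_coefficients(order)
            for k in range(order - 1, n):
                u_bdf = sum(wi * hist[-1 - i] for i, wi in enumerate(w))
                u = u_bdf / (a - dt * lam)
                hist.append(u)
                if len(hist) > 3:
                    hist.pop(0)
            return hist[-1]

        exact = np.exp(lam)
        errs = [abs(integrate(dt) - exact) for dt in (0.02, 0.01, 0.005)]
        p_obs = np.log2(errs[0] / errs[1])
        p_obs2 = np.log2(errs[1] / errs[2])
        assert p_obs == pytest.approx(order, rel=0.1)
        assert p_obs2 == pytest.approx(order, rel=0.1)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            bdf_coefficients(4)


class TestConservationAndEquilibrium:
    def test_pure_diffusion_conserves_mean(self, small_sheet):
        sub = substrate.uniform_substrate(small_sheet, 0.7)
        proto = protocols.Protocol([])
        cfg = SolverConfig(dt=0.05, t_end=5.0, disable_ionic=True,
                           store_stride=5.0)
        s = solver.MonodomainSolver(small_sheet, sub, proto, cfg)
        x = small_sheet.nodes[:, 0]
        v0 = -80.0 + 40.0 * np.exp(-((x - 10.0) ** 2) / 8.0)
        res = s.run(v_init=v0)
        m0 = (s.mass @ v0).sum()
        m1 = (s.mass @ res.frames[-1]).sum()
        assert abs(m1 - m0) / abs(m0) < 1e-8
        # the bump actually spread
        assert res.frames[-1].max() < v0.max() - 1.0

    def test_rest_equilibrium_preserved_with_svi(self, small_sheet, rest_state):
        v_rest, state = rest_state
        sub = substrate.uniform_substrate(small_sheet, 0.7)
        n = small_sheet.n_nodes
        st = crn.IonicState(np.repeat(state.gates, n, axis=1),
                            np.repeat(state.conc, n, axis=1))
        cfg = SolverConfig(dt=0.05, t_end=10.0, store_stride=10.0)
        res = solver.MonodomainSolver(small_sheet, sub,
                                      protocols.Protocol([]), cfg).run(
            initial_state=st, v_init=v_rest)
        assert np.abs(res.frames[-1] - v_rest).max() < 0.05

    def test_empty_protocol_no_activation(self, small_sheet):
        sub = substrate.uniform_substrate(small_sheet, 0.7)
        cfg = SolverConfig(dt=0.1, t_end=20.0)
        res = solver.run(small_sheet, sub, protocols.Protocol([]), cfg)
        from cvep import analysis

        amap = analysis.activation_map(res)
        assert amap.n_valid == 0


class TestIonicStepProperties:
    def test_identical_nodes_update_identically(self, rest_state):
        _, state = rest_state
        m = synth.gen_sheet_mesh(2.0, 1.0, 1.0)
        sub = substrate.uniform_substrate(m, 0.7)
        cfg = SolverConfig(dt=0.05, t_end=1.0)
        s = solver.MonodomainSolver(m, sub, protocols.Protocol([]), cfg)
        n = m.n_nodes
        v = np.full(n, -30.0)
        w = np.repeat(state.gates, n, axis=1)
        c = np.repeat(state.conc, n, axis=1)
        w_new = np.empty_like(w)
        c_new = np.empty_like(c)
        s.ionic_step(v, w, w, c, c, 1.0, w_new, c_new)
        assert (w_new == w_new[:, :1]).all()
        assert (c_new == c_new[:, :1]).all()

    def test_frozen_rest_states_unchanged(self, rest_state):
        v_rest, state = rest_state
        m = synth.gen_sheet_mesh(2.0, 1.0, 1.0)
        sub = substrate.uniform_substrate(m, 1.3)  # healthy, scales = 1
        cfg = SolverConfig(dt=0.05, t_end=1.0)
        s = solver.MonodomainSolver(m, sub, protocols.Protocol([]), cfg)
        n = m.n_nodes
        v = np.full(n, v_rest)
        w = np.repeat(state.gates, n, axis=1)
        c = np.repeat(state.conc, n, axis=1)
        w_new = np.empty_like(w)
        c_new = np.empty_like(c)
        s.ionic_step(v, w, w, c, c, 1.0, w_new, c_new)
        assert np.abs(w_new - w).max() < 1e-5
        assert np.abs(c_new - c).max() / c.max() < 1e-7


class TestPropagation:
    def test_planar_speed_constant_along_cable(self, cable_run):
        m, sub, res = cable_run
        from cvep import analysis

        amap = analysis.activation_map(res)
        x = m.nodes[:, 0]
        mid = np.abs(m.nodes[:, 1] - 1.0) < 1e-9
        sel = mid & (x > 8) & (x < 34) & amap.valid
        xs, at = x[sel], amap.at[sel]
        order = np.argsort(xs)
        xs, at = xs[order], at[order]
        # local speeds over 2 mm windows
        dx = 2.0
        speeds = []
        for x0 in np.arange(10, 32, dx):
            seg = (xs >= x0) & (xs < x0 + dx)
            if seg.sum() > 2:
                p = np.polyfit(xs[seg], at[seg], 1)
                speeds.append(1.0 / p[0])
        speeds = np.array(speeds)
        assert speeds.std() / speeds.mean() < 0.02

    def test_doubling_sigma_scales_speed_by_sqrt2(self):
        from cvep import experiments

        h = 0.5
        base = experiments.speed_calibration((0.7,), h=h, c_l=3.0e-4)[0.7]
        # doubling sigma == multiplying CV* by sqrt(2) under the sigma law
        dbl = experiments.speed_calibration((0.7,), h=h, c_l=6.0e-4)[0.7]
        assert dbl / base == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_central_stimulus_fourfold_symmetry(self):
        m = synth.gen_sheet_mesh(20.0, 20.0, 1.0 / 3.0)
        # isotropic coefficients (C_tn = C_l cv^2) so the wave is circular
        iso = substrate.ConductivityCoefficients(3.0e-4, 3.0e-4 * 0.49, "iso")
        sub = substrate.uniform_substrate(m, 0.7, iso)
        proto = protocols.Protocol([protocols.Impulse(
            "sphere", (10.0, 10.0, 0.0), 2.0, 200.0, 5.0, None, 0.0,
            n_pulses=1)])
        cfg = SolverConfig(dt=0.05, t_end=40.0)
        res = solver.run(m, sub, proto, cfg)
        from cvep import analysis

        amap = analysis.activation_map(res)
        nx = int(m.grid["shape"][0])
        at = amap.at.reshape(nx, nx)  # y-major
        rot = np.rot90(at)
        ok = np.isfinite(at) & np.isfinite(rot)
        scale = np.nanmax(at)
        assert np.abs(at[ok] - rot[ok]).max() / scale < 0.02

    def test_bdf1_vs_bdf3_activation_agreement(self):
        m = synth.gen_sheet_mesh(15.0, 2.0, 0.5)
        sub = substrate.uniform_substrate(m, 0.7)
        proto = protocols.Protocol([protocols.Impulse(
            "slab", (1.0, 0.0, 0.0), 2.0, 200.0, 5.0, None, 0.0, n_pulses=1)])
        maps = []
        for order in (1, 3):
            cfg = SolverConfig(dt=0.0125, t_end=45.0, bdf_order=order)
            res = solver.run(m, sub, proto, cfg)
            from cvep import analysis

            maps.append(analysis.activation_map(res))
        both = maps[0].valid & maps[1].valid
        assert np.abs(maps[0].at[both] - maps[1].at[both]).max() <= 0.5

    def test_bitwise_determinism(self):
        m = synth.gen_sheet_mesh(10.0, 2.0, 0.5)
        sub = substrate.uniform_substrate(m, 0.7)
        proto = protocols.Protocol([protocols.Impulse(
            "slab", (1.0, 0.0, 0.0), 2.0, 200.0, 5.0, None, 0.0, n_pulses=1)])
        cfg = SolverConfig(dt=0.05, t_end=30.0)
        r1 = solver.run(m, sub, proto, cfg)
        r2 = solver.run(m, sub, proto, cfg)
        assert np.array_equal(r1.at_time, r2.at_time, equal_nan=True)
        assert np.array_equal(r1.at_slope, r2.at_slope)
        assert r1.config_hash == r2.config_hash

    def test_divergence_reported_with_position(self):
        m = synth.gen_sheet_mesh(4.0, 2.0, 1.0)
        sub = substrate.uniform_substrate(m, 0.7)
        cfg = SolverConfig(dt=0.05, t_end=1.0)
        s = solver.MonodomainSolver(m, sub, protocols.Protocol([]), cfg)
        n = m.n_nodes
        w = np.full((15, n), 0.5)
        c = np.full((5, n), 1.0)
        c[2, 3] = np.nan
        with pytest.raises(FloatingPointError, match="node"):
            s.ionic_step(np.full(n, -80.0), w, w, w.copy(), c, 1.0,
                         np.empty_like(w), np.empty_like(c))


def test_structured_progress_logs(caplog):
    import json
    import logging

    m = synth.gen_sheet_mesh(10.0, 2.0, 0.5)
    sub = substrate.uniform_substrate(m, 0.7)
    proto = protocols.Protocol([protocols.Impulse(
        "slab", (1.0, 0.0, 0.0), 2.0, 200.0, 5.0, None, 0.0, n_pulses=1)])
    cfg = SolverConfig(dt=0.1, t_end=5.0, log_every=10)
    with caplog.at_level(logging.INFO, logger="cvep.solver"):
        solver.run(m, sub, proto, cfg)
    records = [json.loads(r.message) for r in caplog.records
               if r.name == "cvep.solver"]
    assert len(records) == 5
    assert records[0]["step"] == 10
    assert all({"step", "t_ms", "max_abs_dvdt", "v_max_mv"} <= set(r)
               for r in records)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=-0.1)
        with pytest.raises(ValueError):
            SolverConfig(bdf_order=5)

    def test_content_hash_changes_with_dt(self):
        a = SolverConfig(dt=0.05).content_hash()
        b = SolverConfig(dt=0.1).content_hash()
        assert a != b
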