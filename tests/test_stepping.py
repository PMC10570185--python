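"""Scheme one-step formulas, determinism, brushes, blow-up and the run loop."""

import numpy as np
import pytest

from rxdiff.model import BrushEvent
from rxdiff.operators import System
from rxdiff.stepping import (
    BlowUpError,
    FieldState,
    Stepper,
    apply_brush,
    detect_blowup,
    resume,
    run,
)
from conftest import heat_config_2d, scalar_ode_config


class TestOneStepFormulas:
    """du/dt = -u, u0 = 1, dt = 0.1: hand-computed one-step values.  The
    spatially-constant field makes the PDE stepper act as a scalar method."""

    @pytest.mark.parametrize(
        "scheme, expected",
        [
            ("forward_euler", 0.9),                  # 1 - h
            ("midpoint", 0.905),                     # 1 - h + h^2/2
            ("rk4", 0.9048375),                      # 1 - h + h^2/2 - h^3/6 + h^4/24
            ("adams_bashforth2", 0.905),             # startup step = midpoint
        ],
    )
    def test_single_step(self, scheme, expected):
        cfg = scalar_ode_config()
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        new = Stepper(scheme).step(system, state, 0.1)
        assert new.fields["u"] == pytest.approx(expected, abs=1e-12)
        assert new.t == pytest.approx(0.1) and new.step_index == 1

    def test_ab2_second_step_uses_history(self):
        # u1 = 0.905 (midpoint start); u2 = u1 + h(3/2 (-u1) - 1/2 (-u0))
        cfg = scalar_ode_config()
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        st = Stepper("adams_bashforth2")
        s1 = st.step(system, state, 0.1)
        s2 = st.step(system, s1, 0.1)
        expected = 0.905 + 0.1 * (1.5 * (-0.905) - 0.5 * (-1.0))
        assert s2.fields["u"] == pytest.approx(expected, abs=1e-12)


class TestTemporalOrder:
    """Estimated convergence order over a dt-halving sweep against the exact
    solution of the space-discretised system."""

    @staticmethod
    def _order(scheme, n, dt0, T):
        from rxdiff.cases import heat_cosine_semidiscrete, make_heat_cosine_case

        errs = []
        for dt in (dt0, dt0 / 2, dt0 / 4):
            case = make_heat_cosine_case(dx=1.0 / n, dt=dt)
            case.config.numerics.scheme = scheme
            res = run(case.config, T, capture_frames=False)
            sys_ = System(case.config)
            ref = heat_cosine_semidiscrete(case, sys_.grid, res.state.t)
            errs.append(np.abs(res.state.fields["u"] - ref).max())
        p1 = np.log2(errs[0] / errs[1])
        p2 = np.log2(errs[1] / errs[2])
        return (p1 + p2) / 2

    @pytest.mark.parametrize(
        "scheme, n, dt0, T, expected",
        [
            ("forward_euler", 32, 2e-4, 0.05, 1.0),
            ("midpoint", 32, 2e-4, 0.05, 2.0),
            ("adams_bashforth2", 32, 2e-4, 0.05, 2.0),
            ("rk4", 8, 8e-3, 0.48, 4.0),
        ],
    )
    def test_scheme_orders(self, scheme, n, dt0, T, expected):
        assert self._order(scheme, n, dt0, T) == pytest.approx(expected, abs=0.1)


class TestBlowUp:
    def test_finite_state_is_not_blowup(self):
        s = FieldState(fields={"u": np.ones((3, 3))})
        assert detect_blowup(s) is False

    def test_single_nonfinite_entry_detected(self):
        f = np.ones((3, 3))
        f[1, 2] = np.nan
        assert detect_blowup(FieldState(fields={"u": f})) is True

    def test_unstable_heat_run_blows_up_within_200_steps(self):
        cfg = heat_config_2d(nx=16, ic="cos(2*pi*x)*cos(2*pi*y)")
        h = cfg.numerics.dx
        cfg.numerics.dt = 10 * h * h  # 40x the 2D limit h^2/(4D)
        with pytest.raises(BlowUpError) as exc:
            run(cfg, 200 * cfg.numerics.dt, capture_frames=False)
        assert exc.value.step_index <= 200
        assert exc.value.partial is not None


class TestBrush:
    def test_set_disc_covering_domain(self):
        cfg = heat_config_2d(nx=8)
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        ev = BrushEvent(time=0.0, species="u", shape="disc",
                        center=[0.5, 0.5], radius=2.0, value=1.0, mode="set")
        out = apply_brush(state, ev, system.grid)
        assert np.all(out.fields["u"] == 1.0)

    def test_add_zero_is_identity(self):
        cfg = heat_config_2d(nx=8)
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        ev = BrushEvent(time=0.0, species="u", shape="gaussian",
                        center=[0.5, 0.5], radius=0.1, value=0.0, mode="add")
        out = apply_brush(state, ev, system.grid)
        assert np.array_equal(out.fields["u"], state.fields["u"])

    def test_disc_node_count_matches_pointwise_oracle(self):
        cfg = heat_config_2d(nx=50, ic="0")
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        ev = BrushEvent(time=0.0, species="u", shape="disc",
                        center=[0.37, 0.61], radius=0.2, value=1.0, mode="set")
        out = apply_brush(state, ev, system.grid)
        g = system.grid
        count = 0
        for j in range(g.ny):
            for i in range(g.nx):
                if (g.X[j, i] - 0.37) ** 2 + (g.Y[j, i] - 0.61) ** 2 <= 0.2**2:
                    count += 1
        assert int((out.fields["u"] == 1.0).sum()) == count

    def test_unknown_species_rejected(self):
        cfg = heat_config_2d(nx=8)
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        ev = BrushEvent(time=0.0, species="zz", shape="disc")
        with pytest.raises(KeyError):
            apply_brush(state, ev, system.grid)


class TestRunLoop:
    def test_zero_horizon_returns_initial_state(self):
        cfg = heat_config_2d(nx=8)
        res = run(cfg, 0.0)
        assert res.state.step_index == 0 and res.state.t == 0.0
        assert len(res.frames) == 1

    def test_seeded_initial_noise_is_reproducible(self):
        cfg = heat_config_2d(nx=8, ic="rand")
        cfg.seed = 42
        a = run(cfg, 0.0).state.fields["u"]
        b = run(cfg, 0.0).state.fields["u"]
        assert np.array_equal(a, b)
        cfg.seed = 43
        c = run(cfg, 0.0).state.fields["u"]
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize(
        "scheme", ["forward_euler", "midpoint", "adams_bashforth2", "rk4"]
    )
    def test_checkpoint_resume_is_bit_identical(self, scheme):
        cfg = heat_config_2d(nx=12, ic="cos(2*pi*x)*cos(2*pi*y)")
        cfg.numerics.scheme = scheme
        dt = cfg.numerics.dt
        full = run(cfg, 40 * dt, checkpoint_times=[20 * dt], capture_frames=False)
        ck = full.checkpoints[0]
        resumed = resume(ck, cfg, 40 * dt, capture_frames=False)
        assert resumed.state.t == full.state.t
        assert np.array_equal(resumed.state.fields["u"], full.state.fields["u"])

    def test_checkpoint_rejects_foreign_config(self):
        cfg = heat_config_2d(nx=12)
        dt = cfg.numerics.dt
        full = run(cfg, 10 * dt, checkpoint_times=[5 * dt], capture_frames=False)
        other = heat_config_2d(nx=12, D=2.0)
        with pytest.raises(ValueError):
            resume(full.checkpoints[0], other, 10 * dt)

    def test_brush_event_fires_once_at_its_time(self):
        cfg = heat_config_2d(nx=8, ic="0")
        dt = cfg.numerics.dt
        cfg.brush_events = [
            BrushEvent(time=5 * dt, species="u", shape="disc",
                       center=[0.5, 0.5], radius=2.0, value=3.0, mode="set")
        ]
        res = run(cfg, 10 * dt, capture_frames=False)
        assert any(e[0] == "brush" for e in res.events)
        assert res.state.fields["u"].max() > 1.0  # painted mass diffusing

    def test_declared_scheme_switch_mid_run(self):
        cfg = heat_config_2d(nx=8)
        dt = cfg.numerics.dt
        cfg.numerics.scheme_segments = [[0.0, "forward_euler"], [5 * dt, "rk4"]]
        res = run(cfg, 10 * dt, capture_frames=False)
        assert ("scheme", pytest.approx(5 * dt), "rk4") in [
            (e[0], e[1], e[2]) for e in res.events
        ]

    def test_mirror_symmetry_preserved_exactly(self):
        # start from a bitwise-symmetrised field; the symmetric stencil
        # grouping must then preserve mirror symmetry exactly at every step
        cfg = heat_config_2d(nx=24, ic="cos(2*pi*x)")
        system = System(cfg)
        f0 = system.initial_fields()
        f0["u"] = 0.5 * (f0["u"] + f0["u"][:, ::-1])
        assert np.array_equal(f0["u"], f0["u"][:, ::-1])
        res = run(cfg, 50 * cfg.numerics.dt, system=system,
                  initial_state=FieldState(fields=f0), capture_frames=False)
        u = res.state.fields["u"]
        assert np.array_equal(u, u[:, ::-1])

    def test_periodic_mass_conserved_over_1000_steps(self):
        cfg = heat_config_2d(nx=16, bc_kind="periodic",
                             ic="1 + 0.5*sin(2*pi*x)*sin(2*pi*y)")
        cfg.diffusion["u"]["u"] = "1 + 0.5*sin(2*pi*x)*cos(2*pi*y)"
        cfg.numerics.dt = 0.1 * cfg.numerics.dx ** 2 / 6.0
        system = System(cfg)
        res = run(cfg, 1000 * cfg.numerics.dt, system=system, capture_frames=False)
        from rxdiff.viz import compute_integral

        m0 = compute_integral(system.initial_fields()["u"], system.grid)
        m1 = compute_integral(res.state.fields["u"], system.grid)
        assert abs(m1 - m0) <= 1e-12 * abs(m0)
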