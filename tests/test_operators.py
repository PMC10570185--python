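"""Stencils, ghost nodes and RHS assembly, checked against polynomial
exactness, Taylor bounds, a dense flux-form operator matrix and a spectral
derivative oracle."""

import numpy as np
import pytest

from rxdiff.expr import parse
from rxdiff.grid import build_grid, build_mask
from rxdiff.model import (
    BoundaryCondition,
    DomainSpec,
    NumericsSpec,
    SimulationConfig,
    SpeciesDef,
)
from rxdiff.operators import (
    System,
    assemble_rhs,
    central_first_derivative,
    div_D_grad,
    pad_coefficient,
    pad_with_ghosts,
    second_derivative,
    upwind_first_derivative,
)

ZERO = parse("0", set())


def neumann0():
    return {e: ("neumann", ZERO) for e in ("left", "right", "bottom", "top")}


def periodic():
    return {e: ("periodic", None) for e in ("left", "right", "bottom", "top")}


def grid1d(n=16, L=1.0):
    return build_grid(DomainSpec(dimension=1, Lx=L, Ly=None), L / n)


def grid2d(n=16, L=1.0):
    return build_grid(DomainSpec(dimension=2, Lx=L, Ly=L), L / n)


class TestGhosts:
    def test_homogeneous_neumann_mirrors(self):
        g = grid1d(4)
        F = np.array([[1.0, 2.0, 3.0, 4.0]])
        P = pad_with_ghosts(F, neumann0(), g, {})
        assert P[1, 0] == 1.0 and P[1, -1] == 4.0

    def test_periodic_wraps(self):
        g = grid1d(4)
        F = np.array([[1.0, 2.0, 3.0, 4.0]])
        P = pad_with_ghosts(F, periodic(), g, {})
        assert P[1, 0] == 4.0 and P[1, -1] == 1.0

    def test_inhomogeneous_neumann_offsets_by_h_times_g(self):
        g = grid1d(4)
        F = np.array([[1.0, 2.0, 3.0, 4.0]])
        bcs = {e: ("neumann", parse("2", set())) for e in ("left", "right")}
        P = pad_with_ghosts(F, bcs, g, {})
        assert P[1, 0] == pytest.approx(1.0 + g.dx * 2.0)
        assert P[1, -1] == pytest.approx(4.0 + g.dx * 2.0)

    def test_robin_data_may_reference_the_species(self):
        g = grid1d(4)
        F = np.array([[1.0, 2.0, 3.0, 4.0]])
        bcs = {e: ("robin", parse("-u", {"u"})) for e in ("left", "right")}
        P = pad_with_ghosts(F, bcs, g, {"u": F})
        assert P[1, 0] == pytest.approx(1.0 - g.dx * 1.0)
        assert P[1, -1] == pytest.approx(4.0 - g.dx * 4.0)

    def test_dirichlet_zero_heat_boundary_stays_pinned(self):
        # boundary-adjacent nodes fixed at 0 for every step
        from rxdiff.stepping import Stepper, FieldState

        cfg = SimulationConfig(
            species=[SpeciesDef("u")],
            diffusion={"u": {"u": "1"}},
            kinetics={"u": "0"},
            boundary_conditions={
                "u": {e: BoundaryCondition("dirichlet", "0") for e in ("left", "right")}
            },
            domain=DomainSpec(dimension=1, Lx=1.0, Ly=None),
            numerics=NumericsSpec(dx=1 / 32, dt=1e-4, scheme="forward_euler"),
            initial_conditions={"u": "sin(pi*x)"},
        )
        system = System(cfg)
        state = FieldState(fields=system.initial_fields())
        assert state.fields["u"][0, 0] == 0.0 and state.fields["u"][0, -1] == 0.0
        stepper = Stepper("forward_euler")
        for _ in range(20):
            state = stepper.step(system, state, cfg.numerics.dt)
        assert state.fields["u"][0, 0] == 0.0 and state.fields["u"][0, -1] == 0.0
        assert state.fields["u"][0, 1:-1].max() > 0


class TestFirstDerivative:
    def test_constant_field_gives_zero(self):
        g = grid2d(8)
        P = pad_with_ghosts(np.full(g.shape, 3.7), neumann0(), g, {})
        assert np.all(central_first_derivative(P, "x", g) == 0.0)
        assert np.all(central_first_derivative(P, "y", g) == 0.0)

    def test_exact_for_quadratics_in_the_interior(self):
        g = grid1d(16)
        P = pad_with_ghosts(g.X**2, neumann0(), g, {})
        d = central_first_derivative(P, "x", g)
        assert d[:, 1:-1] == pytest.approx(2 * g.X[:, 1:-1], abs=1e-13)

    def test_taylor_remainder_bound_for_sine(self):
        g = grid1d(64)
        F = np.sin(2 * np.pi * g.X)
        P = pad_with_ghosts(F, periodic(), g, {})
        d = central_first_derivative(P, "x", g)
        err = np.abs(d - 2 * np.pi * np.cos(2 * np.pi * g.X)).max()
        assert err < (2 * np.pi) ** 3 * g.dx**2 / 6


class TestUpwind:
    def test_linear_field_exact_both_sides(self):
        g = grid1d(16)
        P = pad_with_ghosts(g.X.copy(), periodic(), g, {})
        for side in ("backward", "forward"):
            d = upwind_first_derivative(P, "x", side, g)
            assert d[:, 1:-1] == pytest.approx(1.0, abs=1e-13)

    def test_constant_gives_zero(self):
        g = grid1d(8)
        P = pad_with_ghosts(np.full(g.shape, 2.0), periodic(), g, {})
        assert np.all(upwind_first_derivative(P, "x", "backward", g) == 0.0)

    def test_backward_on_square_is_2x_minus_h(self):
        g = grid1d(16)
        P = pad_with_ghosts(g.X**2, neumann0(), g, {})
        d = upwind_first_derivative(P, "x", "backward", g)
        assert d[:, 1:-1] == pytest.approx(2 * g.X[:, 1:-1] - g.dx, abs=1e-13)


class TestSecondDerivative:
    def test_polynomial_exactness(self):
        g = grid1d(16)
        P2 = pad_with_ghosts(g.X**2, neumann0(), g, {})
        assert second_derivative(P2, "x", g)[:, 1:-1] == pytest.approx(2.0, abs=1e-11)
        P1 = pad_with_ghosts(3 * g.X.copy(), neumann0(), g, {})
        assert second_derivative(P1, "x", g)[:, 1:-1] == pytest.approx(0.0, abs=1e-11)

    def test_sine_taylor_bound_on_periodic_grid(self):
        g = grid1d(64, L=2 * np.pi)
        F = np.sin(g.X)
        P = pad_with_ghosts(F, periodic(), g, {})
        err = np.abs(second_derivative(P, "x", g) + np.sin(g.X)).max()
        assert err < g.dx**2 / 12 * 1.01  # |f''''| <= 1


class TestDivDGrad:
    def test_constant_D_quadratic_reduces_to_laplacian_value(self):
        g = grid2d(16)
        U = g.X**2 + g.Y**2
        Up = pad_with_ghosts(U, neumann0(), g, {})
        Dp = pad_with_ghosts(np.full(g.shape, 2.0), neumann0(), g, {})
        out = div_D_grad(Dp, Up, g)
        assert out[1:-1, 1:-1] == pytest.approx(8.0, abs=1e-10)

    def test_constant_U_gives_zero_for_any_D(self, rng):
        g = grid2d(12)
        Up = pad_with_ghosts(np.full(g.shape, 1.3), periodic(), g, {})
        Dp = pad_with_ghosts(rng.random(g.shape) + 0.5, periodic(), g, {})
        assert np.abs(div_D_grad(Dp, Up, g)).max() < 1e-13

    def test_linear_D_linear_U_gives_one(self):
        # div(x d/dx x) = d/dx x = 1; the stencil is exact here
        g = grid1d(16)
        Up = pad_with_ghosts(g.X.copy(), neumann0(), g, {})
        Dp = pad_with_ghosts(g.X.copy(), neumann0(), g, {})
        out = div_D_grad(Dp, Up, g)
        assert out[:, 1:-1] == pytest.approx(1.0, abs=1e-11)

    def test_constant_D_identity_with_five_point_laplacian(self, rng):
        g = grid2d(10)
        U = rng.random(g.shape)
        Up = pad_with_ghosts(U, periodic(), g, {})
        c = 0.7
        Dp = pad_with_ghosts(np.full(g.shape, c), periodic(), g, {})
        lap = second_derivative(Up, "x", g) + second_derivative(Up, "y", g)
        out = div_D_grad(Dp, Up, g)
        assert np.abs(out - c * lap).max() <= 1e-14 * np.abs(out).max()

    def test_flux_form_conservation_with_variable_D(self, rng):
        # periodic sum of fluxes vanishes by antisymmetry
        g = grid2d(20)
        U = rng.random(g.shape)
        D = 1.0 + 0.5 * np.sin(2 * np.pi * g.X) * np.cos(2 * np.pi * g.Y)
        Up = pad_with_ghosts(U, periodic(), g, {})
        Dp = pad_with_ghosts(D, periodic(), g, {})
        out = div_D_grad(Dp, Up, g)
        assert abs(out.sum()) <= 1e-12 * np.abs(out).sum()


# ---------------------------------------------------------------------------
# RHS assembly


def _periodic_cfg(species, diffusion, kinetics, n=5, m=6, L=1.0, extra=None):
    cfg = SimulationConfig(
        species=[SpeciesDef(s) for s in species],
        diffusion=diffusion,
        kinetics=kinetics,
        boundary_conditions={},
        domain=DomainSpec(dimension=2, Lx=L, Ly=L * n / m),
        numerics=NumericsSpec(dx=L / m, dt=1e-5, scheme="forward_euler"),
        params=extra or {},
        initial_conditions={s: "0" for s in species},
    )
    return cfg


def dense_flux_operator(D: np.ndarray, grid) -> np.ndarray:
    """Independent dense matrix for div(D grad .) on a periodic grid, built
    from the flux form sum_nb (D_p + D_q)/2 (u_q - u_p)/h^2 by explicit
    loops."""
    ny, nx = grid.shape
    N = ny * nx
    A = np.zeros((N, N))
    d = D.ravel()

    def idx(j, i):
        return (j % ny) * nx + (i % nx)

    for j in range(ny):
        for i in range(nx):
            p = idx(j, i)
            for dj, di, h in ((0, -1, grid.dx), (0, 1, grid.dx),
                              (-1, 0, grid.dy), (1, 0, grid.dy)):
                q = idx(j + dj, i + di)
                w = 0.5 * (d[p] + d[q]) / (h * h)
                A[p, q] += w
                A[p, p] -= w
    return A


class TestAssembleRHS:
    def test_pure_source_no_diffusion(self):
        cfg = _periodic_cfg(["u"], {}, {"u": "1"})
        fields = {"u": np.zeros((5, 6))}
        r = assemble_rhs(fields, cfg)
        assert np.all(r["u"] == 1.0)

    def test_heat_eigenfunction_relation(self):
        # u = cos(pi x / L), homogeneous Neumann: rhs ~ -D (pi/L)^2 u
        from conftest import heat_config_2d

        cfg = heat_config_2d(nx=64, ic="cos(pi*x)")
        system = System(cfg)
        fields = system.initial_fields()
        r = system.rhs(fields, 0.0)["u"]
        expected = -np.pi**2 * fields["u"]
        scale = np.abs(expected).max()
        assert np.abs(r - expected).max() / scale < np.pi**2 * system.grid.dx**2

    @pytest.mark.parametrize(
        "diffusion, params",
        [
            ({"u": {"u": "1"}, "v": {"v": "2"}}, {}),  # constant D
            ({"u": {"u": "1 + 0.5*sin(2*pi*x)*cos(2*pi*y/r)"}, "v": {"v": "2"}},
             {"r": 5 / 6}),  # variable D
            ({"u": {"u": "1", "v": "0.3"}, "v": {"u": "-0.2", "v": "2"}}, {}),  # cross
        ],
        ids=["constant-D", "variable-D", "cross-diffusion"],
    )
    def test_dense_operator_oracle_on_6x5_grid(self, diffusion, params, rng):
        kinetics = {"u": "0.3*u - 0.2*v", "v": "0.1*u + 0.4*v"}
        cfg = _periodic_cfg(["u", "v"], diffusion, kinetics, n=5, m=6, extra=params)
        system = System(cfg)
        g = system.grid
        fields = {"u": rng.random(g.shape), "v": rng.random(g.shape)}
        r = system.rhs(dict(fields), 0.0)

        ctx = system.context(fields, 0.0)
        from rxdiff.expr import evaluate

        expected = {}
        for row in ("u", "v"):
            acc = np.zeros(g.ny * g.nx)
            for col, e in system.diffusion.get(row, {}).items():
                Dfield = system.full(evaluate(e, ctx))
                A = dense_flux_operator(Dfield, g)
                acc = acc + A @ fields[col].ravel()
            acc = acc + np.asarray(evaluate(system.kinetics[row], ctx)).ravel()
            expected[row] = acc.reshape(g.shape)
        for sp in ("u", "v"):
            scale = max(np.abs(expected[sp]).max(), 1.0)
            assert np.abs(r[sp] - expected[sp]).max() <= 1e-12 * scale

    def test_translation_equivariance_is_exact(self, rng):
        cfg = _periodic_cfg(
            ["u"],
            {"u": {"u": "1 + 0.5*u^2/(1 + u^2)"}},
            {"u": "u - u^3"},
            n=8, m=8,
        )
        system = System(cfg)
        F = rng.random((8, 8))
        r = system.rhs({"u": F}, 0.0)["u"]
        r_shift = system.rhs({"u": np.roll(F, (2, 3), axis=(0, 1))}, 0.0)["u"]
        assert np.array_equal(r_shift, np.roll(r, (2, 3), axis=(0, 1)))

    def test_kdv_rhs_matches_spectral_oracle(self):
        from rxdiff.cases import make_kdv_soliton_case

        L = 2 * np.pi
        cfg = make_kdv_soliton_case(c=4.0, L=16 * np.pi, dx=16 * np.pi / 128).config
        # replace the soliton IC by a single harmonic on [0, 2 pi] for a
        # clean spectral comparison
        cfg.domain.Lx = L
        cfg.numerics.dx = L / 128
        cfg.params = {}
        cfg.initial_conditions = {"phi": "sin(x)"}
        system = System(cfg)
        phi = np.sin(system.grid.X)
        r = system.rhs({"phi": phi, "v": np.zeros_like(phi)}, 0.0)["phi"]

        k = np.fft.fftfreq(system.grid.nx, d=system.grid.dx) * 2 * np.pi
        ph = phi[0]
        v_spec = np.real(np.fft.ifft(1j * k * np.fft.fft(ph)))
        rhs_spec = -np.real(np.fft.ifft((1j * k) ** 2 * np.fft.fft(v_spec))) \
            - 6.0 * v_spec * ph
        assert np.abs(r[0] - rhs_spec).max() < 0.01

    def test_rhs_zero_at_masked_and_pinned_nodes(self):
        cfg = _periodic_cfg(["u"], {"u": {"u": "1"}}, {"u": "1"}, n=8, m=8)
        cfg.domain.Ly = 1.0
        cfg.domain.indicator = "heaviside(0.2 - (x-0.5)^2 - (y-0.5)^2)"
        system = System(cfg)
        fields = {"u": system.full(1.0)}
        r = system.rhs(fields, 0.0)["u"]
        assert np.all(r[~system.mask.inside] == 0.0)
        assert np.all(r[system.mask.inside] == 1.0)  # f=1, u constant
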