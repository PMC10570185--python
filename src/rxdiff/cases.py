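"""Analytic validation cases and synthetic test inputs.

Each :class:`AnalyticCase` bundles a runnable configuration with a
closed-form solution (itself an expression over x, t) and per-resolution
error tolerances, so convergence of the solver can be measured without any
external data:

* heat equation with a cosine initial condition and reflecting walls —
  u(x, t) = exp(-D (k pi / L)^2 t) * cos(k pi x / L), the classic
  wavenumber-dependent decay of separation of variables;
* the wave equation with a compact-support pulse and zero initial velocity —
  the d'Alembert solution u = (g(x - c t) + g(x + c t)) / 2 of two
  half-amplitude copies travelling apart, valid before boundary contact;
* the Korteweg-de Vries soliton phi = (c/2) sech^2(sqrt(c)/2 (x - c t - x0)),
  a shape- and speed-preserving travelling wave on a periodic interval
  (single and two-soliton variants).

Gaussian pulses subtract a 1e-12 floor so they have exact compact support
and cannot leak through periodic seams.  A seeded noisy two-level step
image generator feeds the anisotropic-diffusion denoising checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expr import Expr, evaluate, parse
from .model import (
    BoundaryCondition,
    DomainSpec,
    NumericsSpec,
    SimulationConfig,
    SpeciesDef,
    ViewSpec,
)

__all__ = [
    "AnalyticCase",
    "make_heat_cosine_case",
    "heat_cosine_semidiscrete",
    "make_dalembert_case",
    "make_kdv_soliton_case",
    "kdv_two_soliton_config",
    "make_noisy_step_image",
    "peak_position",
    "local_maxima",
    "periodic_displacement",
]


@dataclass
class AnalyticCase:
    config: SimulationConfig
    exact_solution: Expr  # over x (and y where relevant) and t
    tolerances: dict = field(default_factory=dict)  # resolution -> L-inf tolerance

    def exact(self, x, t):
        ctx = dict(self.config.params)
        ctx.update({"x": x, "t": t})
        return evaluate(self.exact_solution, ctx)


def _no_flux(edges=("left", "right")):
    return {e: BoundaryCondition("neumann", "0") for e in edges}


def make_heat_cosine_case(k: int = 1, D: float = 1.0, L: float = 1.0,
                          t_end: float = 0.1, dx: float = 1.0 / 256,
                          dt: float | None = None) -> AnalyticCase:
    """Heat equation, IC cos(k pi x / L), homogeneous Neumann walls.

    The decay factor at t = (L / k pi)^2 / D is exactly 1/e; doubling k
    quadruples the decay exponent.  Default dt is half the explicit
    stability bound dx^2 / (2 D).
    """
    if k < 1 or k != int(k):
        raise ValueError("mode number k must be a positive integer")
    h = L / int(np.floor(L / dx))
    if dt is None:
        dt = 0.5 * h * h / (2.0 * D)
    cfg = SimulationConfig(
        title=f"heat cosine mode k={k}",
        species=[SpeciesDef("u")],
        diffusion={"u": {"u": "D"}},
        kinetics={"u": "0"},
        boundary_conditions={"u": _no_flux()},
        domain=DomainSpec(dimension=1, Lx=L, Ly=None),
        numerics=NumericsSpec(dx=dx, dt=dt, scheme="forward_euler", steps_per_frame=10**9),
        params={"D": D, "k": float(k), "L": L},
        initial_conditions={"u": "cos(k*pi*x/L)"},
        views=[ViewSpec("u", "u")],
    )
    exact = parse("exp(-D*(k*pi/L)^2*t)*cos(k*pi*x/L)", {"x", "t", "D", "k", "L"})
    case = AnalyticCase(config=cfg, exact_solution=exact)
    case.tolerances = {"t_end": t_end}
    return case


def heat_cosine_semidiscrete(case: AnalyticCase, grid, t: float) -> np.ndarray:
    """Exact solution of the *space-discretised* heat-cosine system.

    On the cell-centred grid with mirror ghosts, cos(k pi x / L) is an exact
    eigenvector of the discrete Laplacian with eigenvalue
    lambda_h = -(2 D / h^2) (1 - cos(k pi h / L)), so the method-of-lines ODE
    system evolves it as exp(lambda_h t) cos(k pi x / L).  Measuring a time
    integrator against this reference isolates the temporal error from the
    fixed spatial one.
    """
    p = case.config.params
    D, k, L = p["D"], p["k"], p["L"]
    h = grid.dx
    lam_h = -(2.0 * D / (h * h)) * (1.0 - np.cos(k * np.pi * h / L))
    return np.exp(lam_h * t) * np.cos(k * np.pi * grid.X / L)


def make_dalembert_case(pulse_width: float = 0.05, c: float = 1.0, L: float = 1.0,
                        t_end: float = 0.25, dx: float = 1.0 / 512,
                        dt: float | None = None) -> AnalyticCase:
    """Wave equation u_tt = c^2 u_xx as the first-order system u_t = v,
    v_t = div(c^2 grad u), with a centred compact-support Gaussian pulse and
    zero initial velocity.

    Exact solution before boundary contact: two half-amplitude copies of the
    pulse travelling at speed c in opposite directions.
    """
    x0 = L / 2.0
    transit = (L / 2.0 - 4 * pulse_width) / c
    if t_end >= transit:
        raise ValueError(
            f"t_end={t_end} reaches the boundary (first contact ~{transit:.3g})"
        )
    h = L / int(np.floor(L / dx))
    if dt is None:
        # CFL c dt / h below RK4's imaginary-axis limit, with margin
        dt = 0.5 * h / c
    g = "max(exp(-((XARG - x0)^2)/(2*w^2)) - 1e-12, 0)"
    cfg = SimulationConfig(
        title="d'Alembert pulse",
        species=[SpeciesDef("u"), SpeciesDef("v")],
        diffusion={"v": {"u": "c^2"}},
        kinetics={"u": "v", "v": "0"},
        boundary_conditions={
            "u": _no_flux(),
            "v": _no_flux(),
        },
        domain=DomainSpec(dimension=1, Lx=L, Ly=None),
        numerics=NumericsSpec(dx=dx, dt=dt, scheme="rk4", steps_per_frame=10**9),
        params={"c": c, "x0": x0, "w": pulse_width},
        initial_conditions={"u": g.replace("XARG", "x"), "v": "0"},
        views=[ViewSpec("u", "u")],
    )
    exact_src = "0.5*(" + g.replace("XARG", "(x - c*t)") + " + " + g.replace(
        "XARG", "(x + c*t)"
    ) + ")"
    exact = parse(exact_src, {"x", "t", "c", "x0", "w"})
    case = AnalyticCase(config=cfg, exact_solution=exact)
    case.tolerances = {"t_end": t_end}
    return case


def _soliton(cvar: str, xvar: str) -> str:
    # (c/2) sech^2(sqrt(c)/2 * xi) written via tanh: sech^2 = 1 - tanh^2
    return f"({cvar}/2)*(1 - tanh(sqrt({cvar})/2*({xvar}))^2)"


def make_kdv_soliton_case(c: float = 4.0, L: float = 50.0,
                          dx: float | None = None,
                          dt: float | None = None) -> AnalyticCase:
    """Single KdV soliton phi_t = -phi_xxx - 6 phi phi_x on a periodic
    interval, posed as phi_t = -v_xx - 6 v phi with algebraic v = phi_x.

    Peak height is c/2, the transit time across the interval is L/c.  L must
    be wide enough that the sech^2 tails are below 1e-8 at the seam.
    """
    if c <= 0:
        raise ValueError("soliton speed c must be positive")
    x0 = L / 4.0
    # tail amplitude at the seam (distance >= L/4 from the peak)
    if (c / 2) * np.cosh(np.sqrt(c) / 2 * (L / 4.0)) ** -2 > 1e-8:
        raise ValueError("domain too small: soliton tails exceed 1e-8 at the seam")
    if dx is None:
        dx = L / 512
    h = L / int(np.floor(L / dx))
    if dt is None:
        # dispersive stability: |lambda|max = max sin(xi)(2-2cos(xi))/h^3 ~ 2.60/h^3,
        # RK4 imaginary-axis bound 2*sqrt(2); keep a 2x margin
        dt = 0.5 * 2.0 * np.sqrt(2.0) / (2.60 / h**3 + 6.0 * (c / 2) / h)
    cfg = SimulationConfig(
        title="KdV single soliton",
        species=[
            SpeciesDef("phi"),
            SpeciesDef("v", role="algebraic", algebraic_rhs="phi_x"),
        ],
        diffusion={},
        kinetics={"phi": "-v_xx - 6*v*phi"},
        boundary_conditions={},  # periodic by default
        domain=DomainSpec(dimension=1, Lx=L, Ly=None),
        numerics=NumericsSpec(dx=dx, dt=dt, scheme="rk4", steps_per_frame=10**9),
        params={"c": c, "x0": x0},
        initial_conditions={"phi": _soliton("c", "(x - x0)")},
        views=[ViewSpec("phi", "phi")],
    )
    exact = parse(
        _soliton("c", "(x - c*t - x0)"), {"x", "t", "c", "x0"}
    )
    return AnalyticCase(config=cfg, exact_solution=exact)


def kdv_two_soliton_config(c1: float = 4.0, c2: float = 2.0, L: float = 50.0,
                           dx: float | None = None,
                           dt: float | None = None) -> SimulationConfig:
    """Two well-separated solitons with c1 > c2; the faster overtakes the
    slower within L / (c1 - c2) time and both emerge with their heights."""
    if not c1 > c2 > 0:
        raise ValueError("need c1 > c2 > 0")
    base = make_kdv_soliton_case(c=c1, L=L, dx=dx, dt=dt)
    cfg = base.config
    cfg.title = "KdV two-soliton collision"
    cfg.params = {"c1": c1, "c2": c2, "x1": L / 4.0, "x2": L / 2.0}
    cfg.initial_conditions = {
        "phi": _soliton("c1", "(x - x1)") + " + " + _soliton("c2", "(x - x2)")
    }
    return cfg


def peak_position(field_1d: np.ndarray, xs: np.ndarray, L: float) -> tuple[float, float]:
    """(location, height) of the largest local maximum of a 1D profile on a
    periodic interval, refined by fitting a parabola through the maximal node
    and its two periodic neighbours."""
    f = np.asarray(field_1d).ravel()
    xs = np.asarray(xs).ravel()
    i = int(np.argmax(f))
    fm, f0, fp = f[i - 1], f[i], f[(i + 1) % f.size]
    denom = fm - 2 * f0 + fp
    delta = 0.0 if denom == 0 else 0.5 * (fm - fp) / denom
    h = xs[1] - xs[0]
    height = f0 - 0.25 * (fm - fp) * delta
    return (xs[i] + delta * h) % L, float(height)


def local_maxima(field_1d: np.ndarray, xs: np.ndarray, threshold: float) -> list:
    """(x, height) of strict local maxima above ``threshold`` (periodic)."""
    f = np.asarray(field_1d).ravel()
    up = f > np.roll(f, 1)
    down = f > np.roll(f, -1)
    out = []
    for i in np.flatnonzero(up & down & (f > threshold)):
        fm, f0, fp = f[i - 1], f[i], f[(i + 1) % f.size]
        denom = fm - 2 * f0 + fp
        delta = 0.0 if denom == 0 else 0.5 * (fm - fp) / denom
        out.append((xs.ravel()[i] + delta * (xs.ravel()[1] - xs.ravel()[0]),
                    float(f0 - 0.25 * (fm - fp) * delta)))
    return out


def periodic_displacement(x0: float, x1: float, L: float) -> float:
    """Signed displacement from x0 to x1 on a circle of circumference L,
    in (-L/2, L/2]."""
    d = (x1 - x0) % L
    return d - L if d > L / 2 else d


def make_noisy_step_image(n: int = 64, noise_sd: float = 0.1, seed: int = 0,
                          low: float = 0.25, high: float = 0.75,
                          path=None) -> np.ndarray:
    """n x n two-level step (left half ``low``, right half ``high``) plus
    seeded Gaussian noise, clipped to [0, 1].  Written as an 8-bit PNG when
    ``path`` is given; returns the float image either way."""
    rng = np.random.default_rng(seed)
    img = np.full((n, n), low)
    img[:, n // 2:] = high
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, (img * 255).round().astype(np.uint8))
    return img
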