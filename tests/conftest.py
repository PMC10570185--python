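import numpy as np
import pytest

from rxdiff.model import (
    BoundaryCondition,
    DomainSpec,
    NumericsSpec,
    SimulationConfig,
    SpeciesDef,
    ViewSpec,
)


def heat_config_2d(nx=32, D=1.0, bc_kind="neumann", ic="cos(2*pi*x)",
                   dt=None, L=1.0):
    """Small 2D heat-equation config used across the suite."""
    dx = L / nx
    if dt is None:
        dt = 0.2 * dx * dx / (4.0 * D)
    bcs = {}
    if bc_kind != "periodic":
        bcs = {
            "u": {
                e: BoundaryCondition(bc_kind, "0")
                for e in ("left", "right", "bottom", "top")
            }
        }
    return SimulationConfig(
        species=[SpeciesDef("u")],
        diffusion={"u": {"u": "D"}},
        kinetics={"u": "0"},
        boundary_conditions=bcs,
        domain=DomainSpec(dimension=2, Lx=L, Ly=L),
        numerics=NumericsSpec(dx=dx, dt=dt, scheme="forward_euler",
                              steps_per_frame=10**9),
        params={"D": D},
        initial_conditions={"u": ic},
        views=[ViewSpec("u", "u")],
    )


def scalar_ode_config(f="-u", u0="1", dt=0.1):
    """A spatially-constant 1-species system: every node follows du/dt = f(u),
    so the PDE stepper reproduces scalar one-step formulas exactly."""
    return SimulationConfig(
        species=[SpeciesDef("u")],
        diffusion={},
        kinetics={"u": f},
        boundary_conditions={},
        domain=DomainSpec(dimension=1, Lx=1.0, Ly=None),
        numerics=NumericsSpec(dx=0.125, dt=dt, scheme="forward_euler",
                              steps_per_frame=10**9),
        params={},
        initial_conditions={"u": u0},
        views=[],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
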