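"""Node lattice and indicator-function domain mask.

The rectangular domain [0, Lx] x [0, Ly] is split into an
(floor(Lx/dx), floor(Ly/dx)) grid — one user step size for both axes,
rounding down — with nodes at cell centres x_i = (i + 1/2) * dx_eff where
dx_eff = Lx / Nx.  Cell-centre placement makes periodic wrap, masking and
midpoint quadrature uniform; it is documented prominently because analytic
comparisons depend on it.

Fields are numpy arrays of shape (Ny, Nx); 1D grids have Ny = 1 and Ly is
treated as 1 so that the quadrature weight dx_eff * dy_eff stays valid.

Non-rectangular domains are subsets of the rectangle: a node is simulated
iff the indicator expression is positive at its coordinates.  Edges between
a simulated and an excluded node are handled by the same ghost mechanism as
the outer boundary, defaulting to zero flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expr import Expr, evaluate
from .model import DomainSpec

__all__ = ["Grid", "DomainMask", "build_grid", "build_mask", "GridError"]


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class Grid:
    dimension: int
    nx: int
    ny: int
    dx: float  # effective spacing Lx/nx
    dy: float  # effective spacing Ly/ny (1D: Ly treated as 1 with ny=1)
    Lx: float
    Ly: float
    X: np.ndarray = field(compare=False, repr=False)
    Y: np.ndarray = field(compare=False, repr=False)

    @property
    def shape(self):
        return (self.ny, self.nx)


@dataclass(frozen=True)
class DomainMask:
    """Boolean node mask (True = simulated) with neighbour-validity fields."""

    inside: np.ndarray = field(repr=False)
    # for each direction, True where the neighbour on that side is simulated
    # (or lies beyond the outer boundary, where ghosts take over)
    nb_left: np.ndarray = field(repr=False)
    nb_right: np.ndarray = field(repr=False)
    nb_down: np.ndarray = field(repr=False)
    nb_up: np.ndarray = field(repr=False)

    @property
    def all_inside(self) -> bool:
        return bool(self.inside.all())

    @property
    def count(self) -> int:
        return int(self.inside.sum())


def build_grid(domain: DomainSpec, dx: float) -> Grid:
    """Build the node lattice with the floor rounding rule."""
    if dx <= 0:
        raise GridError("dx must be > 0")
    if domain.Lx is None or domain.Lx <= 0:
        raise GridError("Lx must be > 0")
    nx = int(np.floor(domain.Lx / dx))
    if nx < 1:
        raise GridError(f"dx={dx} gives no nodes along x (Lx={domain.Lx})")
    if domain.dimension == 1:
        ny, Ly = 1, 1.0
    else:
        if domain.Ly is None or domain.Ly <= 0:
            raise GridError("Ly must be > 0 for 2D domains")
        Ly = float(domain.Ly)
        ny = int(np.floor(Ly / dx))
        if ny < 1:
            raise GridError(f"dx={dx} gives no nodes along y (Ly={Ly})")
    dxe = domain.Lx / nx
    dye = Ly / ny
    xs = (np.arange(nx) + 0.5) * dxe
    ys = (np.arange(ny) + 0.5) * dye
    X, Y = np.meshgrid(xs, ys)
    return Grid(
        dimension=domain.dimension,
        nx=nx,
        ny=ny,
        dx=dxe,
        dy=dye,
        Lx=float(domain.Lx),
        Ly=Ly,
        X=X,
        Y=Y,
    )


def build_mask(indicator: Expr | None, grid: Grid, ctx: dict | None = None) -> DomainMask:
    """Evaluate the indicator at every node; simulated iff value > 0.

    ``ctx`` supplies parameter values (and image samplers) the indicator may
    reference.  An absent indicator yields the all-true mask.  Raises
    :class:`GridError` if no node is inside.
    """
    if indicator is None:
        inside = np.ones(grid.shape, dtype=bool)
    else:
        env = {"x": grid.X, "y": grid.Y}
        if ctx:
            env.update(ctx)
        vals = np.broadcast_to(np.asarray(evaluate(indicator, env), dtype=float), grid.shape)
        inside = vals > 0
    if not inside.any():
        raise GridError("domain indicator excludes every node")

    def shifted(axis, step):
        # neighbour-inside map; beyond the outer rectangle counts as valid
        # (ghost nodes encode the outer BCs there)
        out = np.ones_like(inside)
        if step == -1:
            if axis == 1:
                out[:, 1:] = inside[:, :-1]
            else:
                out[1:, :] = inside[:-1, :]
        else:
            if axis == 1:
                out[:, :-1] = inside[:, 1:]
            else:
                out[:-1, :] = inside[1:, :]
        return out

    return DomainMask(
        inside=inside,
        nb_left=shifted(1, -1),
        nb_right=shifted(1, +1),
        nb_down=shifted(0, -1),
        nb_up=shifted(0, +1),
    )
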