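"""Spatial finite-difference operators and right-hand-side assembly.

One ghost layer per edge encodes the boundary conditions (nodes sit at cell
centres, so the wall lies halfway between the boundary-adjacent node and its
ghost):

* periodic — ghost wraps to the opposite edge;
* neumann / robin with data g — ``ghost = mirror + h * g`` where ``mirror``
  is the boundary-adjacent node and g is the outward-normal derivative,
  evaluated at that node (g may reference the species itself for robin);
* dirichlet — the boundary-adjacent node is pinned to the data value and its
  time derivative forced to zero; operators are left untouched.

The variable-coefficient diffusion stencil is, per axis,

    (1 / 2 h^2) * { D_c [u_l - 2 u_c + u_r] + D_l [u_l - u_c] + D_r [u_r - u_c] }

which is algebraically the conservative flux form
sum_nb (D_c + D_nb)/2 * (u_nb - u_c) / h^2 and reduces to D times the
standard second-order 5-point Laplacian when D is constant.  The symmetric
grouping ``D_c*((u_l + u_r) - 2 u_c) + (D_l*(u_l - u_c) + D_r*(u_r - u_c))``
is used so that mirror-symmetric data produce bitwise mirror-symmetric
results.

At edges between a simulated node and a node excluded by the domain mask the
excluded neighbour's value (and diffusivity) is replaced by the centre
value, which zeroes the flux across that edge — the zero-flux default for
masked internal boundaries.

All arithmetic is double precision.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from .expr import Expr, derivative_token, evaluate, parse
from .grid import Grid, DomainMask, build_grid, build_mask
from .model import (
    SimulationConfig,
    algebraic_order,
    validate_config,
)

__all__ = [
    "pad_with_ghosts",
    "pad_coefficient",
    "central_first_derivative",
    "upwind_first_derivative",
    "second_derivative",
    "div_D_grad",
    "EvalContext",
    "System",
    "assemble_rhs",
]


# ---------------------------------------------------------------------------
# ghost padding

def _edge_data(expr_field, edge):
    """Slice a grid-shaped array down to the boundary-adjacent line."""
    if edge == "left":
        return expr_field[:, 0]
    if edge == "right":
        return expr_field[:, -1]
    if edge == "bottom":
        return expr_field[0, :]
    return expr_field[-1, :]


def pad_with_ghosts(F: np.ndarray, bcs: dict, grid: Grid, ctx) -> np.ndarray:
    """Return F with one ghost layer per edge, shape (ny+2, nx+2).

    ``bcs`` maps edge -> (kind, data Expr or None); ``ctx`` resolves symbols
    in the data expressions (coordinates, t, params, species values).
    On 1D grids the y ghost rows are mirror copies (never differentiated).
    """
    ny, nx = F.shape
    P = np.empty((ny + 2, nx + 2), dtype=F.dtype)
    P[1:-1, 1:-1] = F

    def g_values(expr, edge):
        vals = np.asarray(evaluate(expr, ctx), dtype=float)
        vals = np.broadcast_to(vals, F.shape)
        return _edge_data(vals, edge)

    for edge in ("left", "right"):
        kind, data = bcs.get(edge, ("periodic", None))
        mirror = F[:, 0] if edge == "left" else F[:, -1]
        tgt = (slice(1, -1), 0) if edge == "left" else (slice(1, -1), -1)
        if kind == "periodic":
            P[tgt] = F[:, -1] if edge == "left" else F[:, 0]
        elif kind in ("neumann", "robin"):
            P[tgt] = mirror + grid.dx * g_values(data, edge)
        else:  # dirichlet: node pinned elsewhere; reflect
            P[tgt] = mirror

    if grid.dimension == 2:
        for edge in ("bottom", "top"):
            kind, data = bcs.get(edge, ("periodic", None))
            mirror = F[0, :] if edge == "bottom" else F[-1, :]
            tgt = (0, slice(1, -1)) if edge == "bottom" else (-1, slice(1, -1))
            if kind == "periodic":
                P[tgt] = F[-1, :] if edge == "bottom" else F[0, :]
            elif kind in ("neumann", "robin"):
                P[tgt] = mirror + grid.dy * g_values(data, edge)
            else:
                P[tgt] = mirror
    else:
        P[0, 1:-1] = F[0, :]
        P[-1, 1:-1] = F[-1, :]

    # corners are never read by the 5-point stencils; fill for finiteness
    P[0, 0] = P[1, 1]
    P[0, -1] = P[1, -2]
    P[-1, 0] = P[-2, 1]
    P[-1, -1] = P[-2, -2]
    return P


def pad_coefficient(D: np.ndarray, bc_kinds: dict, grid: Grid) -> np.ndarray:
    """Pad a coefficient field: wrap on periodic edges, mirror otherwise."""
    bcs = {}
    for edge in ("left", "right", "bottom", "top"):
        kind = bc_kinds.get(edge, "periodic")
        bcs[edge] = ("periodic", None) if kind == "periodic" else ("dirichlet", None)
    return pad_with_ghosts(D, bcs, grid, {})


# ---------------------------------------------------------------------------
# stencils

def _neighbours(P, mask: DomainMask | None):
    """Centre and 4 neighbour views of a padded array, with excluded
    neighbours replaced by the centre value (zero-flux mask edges)."""
    C = P[1:-1, 1:-1]
    L = P[1:-1, :-2]
    R = P[1:-1, 2:]
    D = P[:-2, 1:-1]
    U = P[2:, 1:-1]
    if mask is not None and not mask.all_inside:
        L = np.where(mask.nb_left, L, C)
        R = np.where(mask.nb_right, R, C)
        D = np.where(mask.nb_down, D, C)
        U = np.where(mask.nb_up, U, C)
    return C, L, R, D, U


def central_first_derivative(P, axis: str, grid: Grid, mask=None):
    """(F(.+h) - F(.-h)) / 2h at every node; ``axis`` is 'x' or 'y'."""
    C, L, R, D, U = _neighbours(P, mask)
    if axis == "x":
        return (R - L) / (2.0 * grid.dx)
    return (U - D) / (2.0 * grid.dy)


def upwind_first_derivative(P, axis: str, side: str, grid: Grid, mask=None):
    """One-sided first difference; ``side`` is 'backward' or 'forward'."""
    C, L, R, D, U = _neighbours(P, mask)
    if axis == "x":
        return (C - L) / grid.dx if side == "backward" else (R - C) / grid.dx
    return (C - D) / grid.dy if side == "backward" else (U - C) / grid.dy


def second_derivative(P, axis: str, grid: Grid, mask=None):
    """(F(.-h) - 2F(.) + F(.+h)) / h^2."""
    C, L, R, D, U = _neighbours(P, mask)
    if axis == "x":
        return ((L + R) - 2.0 * C) / (grid.dx * grid.dx)
    return ((D + U) - 2.0 * C) / (grid.dy * grid.dy)


def div_D_grad(D_padded, U_padded, grid: Grid, mask: DomainMask | None = None):
    """Variable-coefficient diffusion stencil div(D grad u) (see module doc)."""
    Uc, Ul, Ur, Ud, Uu = _neighbours(U_padded, mask)
    Dc, Dl, Dr, Dd, Du = _neighbours(D_padded, mask)
    out = (
        Dc * ((Ul + Ur) - 2.0 * Uc) + (Dl * (Ul - Uc) + Dr * (Ur - Uc))
    ) / (2.0 * grid.dx * grid.dx)
    if grid.dimension == 2:
        out = out + (
            Dc * ((Ud + Uu) - 2.0 * Uc) + (Dd * (Ud - Uc) + Du * (Uu - Uc))
        ) / (2.0 * grid.dy * grid.dy)
    return out


# ---------------------------------------------------------------------------
# evaluation context

_DERIV_OPS = {
    "x": ("x", None),
    "y": ("y", None),
    "xx": ("x", "second"),
    "yy": ("y", "second"),
    "x_b": ("x", "backward"),
    "x_f": ("x", "forward"),
    "y_b": ("y", "backward"),
    "y_f": ("y", "forward"),
}


class EvalContext(Mapping):
    """Resolves every symbol an expression may reference against the current
    state: species values, coordinates, time, parameters, image samplers and
    derivative tokens (computed on demand from ghost-padded fields and
    cached)."""

    def __init__(self, system: "System", fields: dict, t: float):
        self.system = system
        self.fields = fields
        self.t = t
        self._padded: dict[str, np.ndarray] = {}
        self._derivs: dict[str, np.ndarray] = {}

    def padded(self, sp: str) -> np.ndarray:
        if sp not in self._padded:
            self._padded[sp] = pad_with_ghosts(
                self.fields[sp], self.system.bcs[sp], self.system.grid, self
            )
        return self._padded[sp]

    def __getitem__(self, name):
        if name in self.fields:
            return self.fields[name]
        sys = self.system
        if name == "x":
            return sys.grid.X
        if name == "y":
            return sys.grid.Y
        if name == "t":
            return self.t
        if name in sys.params:
            return sys.params[name]
        if name in sys.samplers:
            return sys.samplers[name]
        tok = derivative_token(name, sys.species_names)
        if tok and name not in self._derivs:
            sp, suf = tok
            axis, mode = _DERIV_OPS[suf]
            P = self.padded(sp)
            if mode == "second":
                val = second_derivative(P, axis, sys.grid, sys.mask)
            elif mode is None:
                val = central_first_derivative(P, axis, sys.grid, sys.mask)
            else:
                val = upwind_first_derivative(P, axis, mode, sys.grid, sys.mask)
            self._derivs[name] = val
        if tok:
            return self._derivs[name]
        raise KeyError(name)

    def __iter__(self):  # pragma: no cover - Mapping protocol
        return iter(self.fields)

    def __len__(self):  # pragma: no cover
        return len(self.fields)


# ---------------------------------------------------------------------------
# compiled system

class System:
    """A validated config compiled to parsed expressions, grid, mask and BC
    tables, exposing the method-of-lines right-hand side."""

    def __init__(self, cfg: SimulationConfig, check: bool = True):
        if check:
            diags = validate_config(cfg)
            if diags:
                raise ValueError(
                    "invalid configuration:\n" + "\n".join(str(d) for d in diags)
                )
        self.cfg = cfg
        self.grid = build_grid(cfg.domain, cfg.numerics.dx)
        self.params = dict(cfg.params)
        self.species_names = cfg.species_names()
        self.differential = cfg.differential_species()
        self.alg_order = algebraic_order(cfg)
        self.samplers = self._load_samplers(cfg)

        from .model import _base_symbols, _kinetics_symbols  # symbol policies

        kin_syms = _kinetics_symbols(cfg)
        base_syms = _base_symbols(cfg)

        self.diffusion: dict[str, dict[str, Expr]] = {
            row: {col: parse(src, kin_syms) for col, src in cols.items()}
            for row, cols in cfg.diffusion.items()
        }
        self.kinetics: dict[str, Expr] = {
            sp: parse(src, kin_syms) for sp, src in cfg.kinetics.items()
        }
        self.algebraic: dict[str, Expr] = {
            s.name: parse(s.algebraic_rhs, kin_syms) for s in cfg.algebraic_species()
        }
        self.bcs: dict[str, dict[str, tuple]] = {}
        self.bc_kinds: dict[str, dict[str, str]] = {}
        for sp in self.species_names:
            per, kinds = {}, {}
            for edge in cfg.edges():
                bc = cfg.bc(sp, edge)
                data = None if bc.kind == "periodic" else parse(bc.value, base_syms)
                per[edge] = (bc.kind, data)
                kinds[edge] = bc.kind
            self.bcs[sp] = per
            self.bc_kinds[sp] = kinds

        ind = None
        if cfg.domain.indicator is not None:
            ind_syms = {"x", "y"} | set(self.params) | set(self.samplers)
            ind = parse(cfg.domain.indicator, ind_syms)
        ind_ctx = dict(self.params)
        ind_ctx.update(self.samplers)
        self.mask = build_mask(ind, self.grid, ind_ctx)

        ic_syms = {"x", "y", "rand"} | set(self.params) | set(self.samplers)
        self.ics: dict[str, Expr] = {
            sp: parse(src, ic_syms) for sp, src in cfg.initial_conditions.items()
        }

        # dirichlet bookkeeping: pinned-node masks and per-edge data
        self.pinned: dict[str, np.ndarray] = {}
        self._dirichlet_edges: dict[str, list] = {}
        for sp in self.species_names:
            edges = [
                (edge, self.bcs[sp][edge][1])
                for edge in cfg.edges()
                if self.bcs[sp][edge][0] == "dirichlet"
            ]
            if edges:
                pin = np.zeros(self.grid.shape, dtype=bool)
                for edge, _ in edges:
                    if edge == "left":
                        pin[:, 0] = True
                    elif edge == "right":
                        pin[:, -1] = True
                    elif edge == "bottom":
                        pin[0, :] = True
                    else:
                        pin[-1, :] = True
                self.pinned[sp] = pin & self.mask.inside
                self._dirichlet_edges[sp] = edges

    @staticmethod
    def _load_samplers(cfg) -> dict:
        if not cfg.images:
            return {}
        from .io import load_image_function  # local import; io imports viz types

        out = {}
        for key, path in cfg.images.items():
            out[key] = load_image_function(path, cfg.domain).sampler
        return out

    # -- state helpers -----------------------------------------------------
    def full(self, value) -> np.ndarray:
        out = np.empty(self.grid.shape, dtype=float)
        out[...] = value
        return out

    def context(self, fields: dict, t: float) -> EvalContext:
        return EvalContext(self, fields, t)

    def update_algebraic(self, fields: dict, t: float) -> None:
        for name in self.alg_order:
            ctx = self.context(fields, t)
            fields[name] = self.full(evaluate(self.algebraic[name], ctx))

    def pin_dirichlet(self, fields: dict, t: float) -> None:
        for sp, edges in self._dirichlet_edges.items():
            ctx = self.context(fields, t)
            F = fields[sp]
            for edge, data in edges:
                vals = np.broadcast_to(
                    np.asarray(evaluate(data, ctx), dtype=float), self.grid.shape
                )
                if edge == "left":
                    F[:, 0] = vals[:, 0]
                elif edge == "right":
                    F[:, -1] = vals[:, -1]
                elif edge == "bottom":
                    F[0, :] = vals[0, :]
                else:
                    F[-1, :] = vals[-1, :]

    def prepare(self, fields: dict, t: float) -> None:
        """Bring a raw state to a consistent one: dirichlet values pinned,
        algebraic species recomputed."""
        self.pin_dirichlet(fields, t)
        self.update_algebraic(fields, t)

    def initial_fields(self, seed: int | None = None) -> dict:
        seed = self.cfg.seed if seed is None else seed
        fields: dict[str, np.ndarray] = {}
        for i, sp in enumerate(self.species_names):
            fields[sp] = np.zeros(self.grid.shape)
        for i, sp in enumerate(self.differential):
            e = self.ics.get(sp)
            if e is None:
                continue
            ctx = {"x": self.grid.X, "y": self.grid.Y}
            ctx.update(self.params)
            ctx.update(self.samplers)
            if "rand" in e.free_symbols:
                rng = np.random.default_rng((int(seed) % (2**31), i))
                ctx["rand"] = rng.random(self.grid.shape)
            fields[sp] = self.full(evaluate(e, ctx))
        self.prepare(fields, 0.0)
        return fields

    # -- right-hand side ---------------------------------------------------
    def rhs(self, fields: dict, t: float, prepared: bool = False) -> dict:
        """du/dt for every differential species, zero at masked-out and
        dirichlet-pinned nodes.  Recomputes algebraic species first."""
        with np.errstate(all="ignore"):
            return self._rhs(fields, t, prepared)

    def _rhs(self, fields: dict, t: float, prepared: bool) -> dict:
        if not prepared:
            self.prepare(fields, t)
        ctx = self.context(fields, t)
        out: dict[str, np.ndarray] = {}
        for sp in self.differential:
            acc = np.zeros(self.grid.shape)
            for col, Dexpr in self.diffusion.get(sp, {}).items():
                Dfield = self.full(evaluate(Dexpr, ctx))
                Dp = pad_coefficient(Dfield, self.bc_kinds[col], self.grid)
                Up = ctx.padded(col)
                acc = acc + div_D_grad(Dp, Up, self.grid, self.mask)
            f = self.kinetics.get(sp)
            if f is not None:
                acc = acc + evaluate(f, ctx)
            if not self.mask.all_inside:
                acc = np.where(self.mask.inside, acc, 0.0)
            if sp in self.pinned:
                acc = np.where(self.pinned[sp], 0.0, acc)
            out[sp] = acc
        return out

    def stable_dt_advisory(self, fields: dict | None = None) -> float | None:
        """Heuristic explicit-diffusion stability bound dt <= h^2/(2 d Dmax),
        with D estimated on the initial state.  Advisory only."""
        if not any(self.diffusion.values()):
            return None
        if fields is None:
            fields = self.initial_fields()
        ctx = self.context(fields, 0.0)
        dmax = 0.0
        for cols in self.diffusion.values():
            for e in cols.values():
                vals = np.asarray(evaluate(e, ctx), dtype=float)
                finite = vals[np.isfinite(vals)] if vals.ndim else vals
                if np.size(finite):
                    dmax = max(dmax, float(np.max(np.abs(finite))))
        if dmax == 0.0:
            return None
        h2 = min(self.grid.dx, self.grid.dy if self.grid.dimension == 2 else self.grid.dx) ** 2
        return h2 / (2 * self.grid.dimension * dmax)


def assemble_rhs(state, cfg: SimulationConfig, t: float | None = None) -> dict:
    """One-shot RHS assembly for a state (a FieldState or a fields dict)."""
    system = System(cfg)
    if hasattr(state, "fields"):
        fields = {k: np.array(v, dtype=float) for k, v in state.fields.items()}
        t = state.t if t is None else t
    else:
        fields = {k: np.array(v, dtype=float) for k, v in state.items()}
        t = 0.0 if t is None else t
    return system.rhs(fields, t)
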