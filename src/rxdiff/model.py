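"""Declarative description of a simulation.

A :class:`SimulationConfig` is the unit of sharing: one plain dict/JSON
document that completely determines a run — the coupled PDE system

    du_i/dt = sum_j  div( D_ij grad u_j ) + f_i(u, grad u, x, y, t)

for the differential species, algebraic species given as explicit
assignments, boundary conditions per species and edge, the rectangular
domain (optionally masked by an indicator function), numerics, parameters,
initial conditions and views.  All formulas are expression strings in the
grammar of :mod:`rxdiff.expr`.

:func:`validate_config` is total: it returns a list of diagnostics and never
raises on malformed-but-parseable input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dfield

from .expr import (
    DERIVATIVE_SUFFIXES,
    IMAGE_FUNCTIONS,
    MIXED_SUFFIXES,
    ExprError,
    derivative_token,
    parse,
)

__all__ = [
    "SpeciesDef",
    "BoundaryCondition",
    "DomainSpec",
    "NumericsSpec",
    "ViewSpec",
    "BrushEvent",
    "SimulationConfig",
    "Diagnostic",
    "validate_config",
    "algebraic_order",
    "AlgebraicCycleError",
    "SCHEMES",
    "BC_KINDS",
    "EDGES_1D",
    "EDGES_2D",
]

SCHEMES = ("forward_euler", "adams_bashforth2", "midpoint", "rk4")
BC_KINDS = ("periodic", "dirichlet", "neumann", "robin")
EDGES_1D = ("left", "right")
EDGES_2D = ("left", "right", "bottom", "top")


class ConfigError(ValueError):
    """Structural error while building a config from a document."""


class AlgebraicCycleError(ValueError):
    """Cyclic dependency among algebraic species."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("algebraic species form a cycle: " + " -> ".join(self.cycle))


@dataclass
class SpeciesDef:
    name: str
    role: str = "differential"  # "differential" | "algebraic"
    algebraic_rhs: str | None = None


@dataclass
class BoundaryCondition:
    kind: str = "periodic"
    value: str = "0"  # expression; boundary value (dirichlet) or normal-derivative data g


@dataclass
class DomainSpec:
    dimension: int = 2
    Lx: float = 1.0
    Ly: float | None = 1.0
    indicator: str | None = None


@dataclass
class NumericsSpec:
    dx: float = 0.01
    dt: float = 1e-5
    scheme: str = "forward_euler"
    steps_per_frame: int = 100
    # optional declarative scheme switching: [[t_start, scheme], ...]
    scheme_segments: list | None = None


@dataclass
class ViewSpec:
    name: str
    expression: str
    colormap: str = "viridis"
    scaling: str | list = "adaptive"  # "adaptive" or [vmin, vmax]
    colorbar: bool = False


@dataclass
class BrushEvent:
    time: float
    species: str
    shape: str  # "disc" | "gaussian"
    center: list = dfield(default_factory=lambda: [0.5, 0.5])
    radius: float = 0.1
    value: float = 1.0
    mode: str = "set"  # "set" | "add"


@dataclass
class SimulationConfig:
    species: list = dfield(default_factory=list)  # [SpeciesDef]
    diffusion: dict = dfield(default_factory=dict)  # {row: {col: expr}}
    kinetics: dict = dfield(default_factory=dict)  # {species: expr}
    boundary_conditions: dict = dfield(default_factory=dict)  # {species: {edge: BC}}
    domain: DomainSpec = dfield(default_factory=DomainSpec)
    numerics: NumericsSpec = dfield(default_factory=NumericsSpec)
    params: dict = dfield(default_factory=dict)
    param_ranges: dict = dfield(default_factory=dict)  # optional slider metadata {p: [lo, hi]}
    initial_conditions: dict = dfield(default_factory=dict)
    views: list = dfield(default_factory=list)  # [ViewSpec]
    brush_events: list = dfield(default_factory=list)  # [BrushEvent]
    images: dict = dfield(default_factory=dict)  # {"I_S"|"I_T": path}
    seed: int = 0
    title: str = ""

    # ---- convenience accessors -------------------------------------------
    def species_names(self):
        return [s.name for s in self.species]

    def differential_species(self):
        return [s.name for s in self.species if s.role == "differential"]

    def algebraic_species(self):
        return [s for s in self.species if s.role == "algebraic"]

    def edges(self):
        return EDGES_1D if self.domain.dimension == 1 else EDGES_2D

    def bc(self, species: str, edge: str) -> BoundaryCondition:
        """BC for a species/edge; species without explicit BCs are periodic."""
        per = self.boundary_conditions.get(species, {})
        return per.get(edge, BoundaryCondition("periodic", "0"))

    # ---- document round trip ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "species": [
                {"name": s.name, "role": s.role, "algebraic_rhs": s.algebraic_rhs}
                for s in self.species
            ],
            "diffusion": {r: dict(cols) for r, cols in self.diffusion.items()},
            "kinetics": dict(self.kinetics),
            "boundary_conditions": {
                sp: {e: {"kind": bc.kind, "value": bc.value} for e, bc in per.items()}
                for sp, per in self.boundary_conditions.items()
            },
            "domain": {
                "dimension": self.domain.dimension,
                "Lx": self.domain.Lx,
                "Ly": self.domain.Ly,
                "indicator": self.domain.indicator,
            },
            "numerics": {
                "dx": self.numerics.dx,
                "dt": self.numerics.dt,
                "scheme": self.numerics.scheme,
                "steps_per_frame": self.numerics.steps_per_frame,
                "scheme_segments": self.numerics.scheme_segments,
            },
            "params": dict(self.params),
            "param_ranges": {k: list(v) for k, v in self.param_ranges.items()},
            "initial_conditions": dict(self.initial_conditions),
            "views": [
                {
                    "name": v.name,
                    "expression": v.expression,
                    "colormap": v.colormap,
                    "scaling": v.scaling,
                    "colorbar": v.colorbar,
                }
                for v in self.views
            ],
            "brush_events": [
                {
                    "time": b.time,
                    "species": b.species,
                    "shape": b.shape,
                    "center": list(b.center),
                    "radius": b.radius,
                    "value": b.value,
                    "mode": b.mode,
                }
                for b in self.brush_events
            ],
            "images": dict(self.images),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        """Build a config from a plain document, rejecting unknown keys."""

        def take(d, allowed, path):
            unknown = set(d) - set(allowed)
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} at {path or 'top level'}"
                )

        take(
            doc,
            [
                "title", "species", "diffusion", "kinetics", "boundary_conditions",
                "domain", "numerics", "params", "param_ranges", "initial_conditions",
                "views", "brush_events", "images", "seed",
            ],
            "",
        )
        species = []
        for i, s in enumerate(doc.get("species", [])):
            take(s, ["name", "role", "algebraic_rhs"], f"species[{i}]")
            species.append(
                SpeciesDef(
                    name=s["name"],
                    role=s.get("role", "differential"),
                    algebraic_rhs=s.get("algebraic_rhs"),
                )
            )
        bcs = {}
        for sp, per in doc.get("boundary_conditions", {}).items():
            bcs[sp] = {}
            for edge, b in per.items():
                take(b, ["kind", "value"], f"boundary_conditions.{sp}.{edge}")
                bcs[sp][edge] = BoundaryCondition(
                    kind=b.get("kind", "periodic"), value=b.get("value", "0")
                )
        dom = doc.get("domain", {})
        take(dom, ["dimension", "Lx", "Ly", "indicator"], "domain")
        num = doc.get("numerics", {})
        take(num, ["dx", "dt", "scheme", "steps_per_frame", "scheme_segments"], "numerics")
        views = []
        for i, v in enumerate(doc.get("views", [])):
            take(v, ["name", "expression", "colormap", "scaling", "colorbar"], f"views[{i}]")
            views.append(
                ViewSpec(
                    name=v["name"],
                    expression=v["expression"],
                    colormap=v.get("colormap", "viridis"),
                    scaling=v.get("scaling", "adaptive"),
                    colorbar=v.get("colorbar", False),
                )
            )
        brushes = []
        for i, b in enumerate(doc.get("brush_events", [])):
            take(
                b,
                ["time", "species", "shape", "center", "radius", "value", "mode"],
                f"brush_events[{i}]",
            )
            brushes.append(
                BrushEvent(
                    time=b["time"],
                    species=b["species"],
                    shape=b.get("shape", "disc"),
                    center=list(b.get("center", [0.5, 0.5])),
                    radius=b.get("radius", 0.1),
                    value=b.get("value", 1.0),
                    mode=b.get("mode", "set"),
                )
            )
        return cls(
            title=doc.get("title", ""),
            species=species,
            diffusion={r: dict(c) for r, c in doc.get("diffusion", {}).items()},
            kinetics=dict(doc.get("kinetics", {})),
            boundary_conditions=bcs,
            domain=DomainSpec(
                dimension=dom.get("dimension", 2),
                Lx=dom.get("Lx", 1.0),
                Ly=dom.get("Ly", 1.0),
                indicator=dom.get("indicator"),
            ),
            numerics=NumericsSpec(
                dx=num.get("dx", 0.01),
                dt=num.get("dt", 1e-5),
                scheme=num.get("scheme", "forward_euler"),
                steps_per_frame=num.get("steps_per_frame", 100),
                scheme_segments=num.get("scheme_segments"),
            ),
            params=dict(doc.get("params", {})),
            param_ranges={k: list(v) for k, v in doc.get("param_ranges", {}).items()},
            initial_conditions=dict(doc.get("initial_conditions", {})),
            views=views,
            brush_events=brushes,
            images=dict(doc.get("images", {})),
            seed=doc.get("seed", 0),
        )


@dataclass(frozen=True)
class Diagnostic:
    field: str
    message: str

    def __str__(self):
        return f"{self.field}: {self.message}"


def algebraic_order(cfg: SimulationConfig) -> list[str]:
    """Topologically order the algebraic species.

    Each algebraic species may reference differential species freely and
    other algebraic species only acyclically.  Raises
    :class:`AlgebraicCycleError` on a cycle (self-reference included).
    """
    alg = {s.name: s for s in cfg.algebraic_species()}
    names = set(cfg.species_names())
    deps: dict[str, set[str]] = {}
    for name, s in alg.items():
        d: set[str] = set()
        if s.algebraic_rhs:
            try:
                e = parse(s.algebraic_rhs, _kinetics_symbols(cfg))
            except ExprError:
                e = None
            if e is not None:
                for sym in e.free_symbols:
                    tok = derivative_token(sym, names)
                    base = tok[0] if tok else sym
                    if base in alg:
                        d.add(base)
        deps[name] = d

    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done
    stack: list[str] = []

    def visit(n):
        if state.get(n) == 1:
            return
        if state.get(n) == 0:
            cyc = stack[stack.index(n):] + [n]
            raise AlgebraicCycleError(cyc)
        state[n] = 0
        stack.append(n)
        for m in sorted(deps[n]):
            visit(m)
        stack.pop()
        state[n] = 1
        order.append(n)

    for n in [s.name for s in cfg.algebraic_species()]:
        visit(n)
    return order


def _base_symbols(cfg: SimulationConfig) -> set[str]:
    syms = set(cfg.species_names()) | set(cfg.params) | {"x", "t"}
    if cfg.domain.dimension == 2:
        syms.add("y")
    syms |= set(cfg.images) & set(IMAGE_FUNCTIONS)
    return syms


def _kinetics_symbols(cfg: SimulationConfig) -> set[str]:
    """Symbols legal in kinetics/views/algebraic definitions (incl. derivative
    tokens; mixed tokens are admitted at parse time so that validation can
    name the no-mixed-derivatives rule rather than report an unknown symbol)."""
    syms = set(_base_symbols(cfg))
    suffixes = DERIVATIVE_SUFFIXES + MIXED_SUFFIXES
    for sp in cfg.species_names():
        for suf in suffixes:
            syms.add(f"{sp}_{suf}")
    return syms


_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def validate_config(cfg: SimulationConfig) -> list[Diagnostic]:
    """Check a structurally complete config; return diagnostics (empty iff runnable)."""
    out: list[Diagnostic] = []
    add = lambda f, m: out.append(Diagnostic(f, m))  # noqa: E731

    names = cfg.species_names()
    if not names:
        add("species", "at least one species is required")
        return out
    if len(set(names)) != len(names):
        add("species", "species names must be unique")
    for s in cfg.species:
        if not _IDENT.match(s.name):
            add("species", f"invalid species name {s.name!r}")
        if s.role not in ("differential", "algebraic"):
            add("species", f"{s.name}: unknown role {s.role!r}")
        if s.role == "algebraic" and not s.algebraic_rhs:
            add("species", f"{s.name}: algebraic species needs algebraic_rhs")
        if s.role == "differential" and s.algebraic_rhs:
            add("species", f"{s.name}: differential species must not set algebraic_rhs")
    if not cfg.differential_species():
        add("species", "at least one species must be differential")

    dom = cfg.domain
    if dom.dimension not in (1, 2):
        add("domain.dimension", f"must be 1 or 2, got {dom.dimension}")
        return out
    if not dom.Lx or dom.Lx <= 0:
        add("domain.Lx", "must be > 0")
    if dom.dimension == 2 and (not dom.Ly or dom.Ly <= 0):
        add("domain.Ly", "must be > 0")

    num = cfg.numerics
    if num.dx <= 0:
        add("numerics.dx", "must be > 0")
    if num.dt <= 0:
        add("numerics.dt", "must be > 0")
    sides = [dom.Lx] + ([dom.Ly] if dom.dimension == 2 else [])
    if num.dx > 0 and all(s and s > 0 for s in sides) and num.dx >= min(sides):
        add("numerics.dx", f"dx={num.dx} must be smaller than the shortest side {min(sides)}")
    if num.scheme not in SCHEMES:
        add("numerics.scheme", f"unknown scheme {num.scheme!r}; choose from {SCHEMES}")
    if num.steps_per_frame < 1:
        add("numerics.steps_per_frame", "must be >= 1")
    if num.scheme_segments is not None:
        prev = None
        for seg in num.scheme_segments:
            try:
                t0, sch = seg
            except (TypeError, ValueError):
                add("numerics.scheme_segments", f"segment {seg!r} is not [t_start, scheme]")
                continue
            if sch not in SCHEMES:
                add("numerics.scheme_segments", f"unknown scheme {sch!r}")
            if prev is not None and t0 <= prev:
                add("numerics.scheme_segments", "segment start times must increase")
            prev = t0

    kin_syms = _kinetics_symbols(cfg)
    base_syms = _base_symbols(cfg)

    def check_expr(field, src, allowed, *, forbid_derivs=False, context=""):
        """Parse and run the symbol-policy checks; returns Expr or None."""
        if src is None:
            add(field, "missing expression")
            return None
        try:
            e = parse(src, allowed)
        except ExprError as err:
            add(field, str(err))
            return None
        for sym in sorted(e.free_symbols):
            tok = derivative_token(sym, names)
            if tok and tok[1] in MIXED_SUFFIXES:
                add(field, f"{sym!r}: mixed spatial derivatives are not supported")
            elif tok and forbid_derivs:
                add(field, f"{sym!r}: derivative tokens are not allowed in {context}")
            elif tok and tok[1] in ("y", "yy", "y_b", "y_f") and dom.dimension == 1:
                add(field, f"{sym!r}: y-derivatives are undefined on a 1D domain")
        return e

    # diffusion matrix
    uses_space = False
    for row, cols in cfg.diffusion.items():
        if row not in names:
            add("diffusion", f"unknown species {row!r} in diffusion rows")
            continue
        if row not in cfg.differential_species():
            add("diffusion", f"diffusion row {row!r} must be a differential species")
        for col, src in cols.items():
            if col not in names:
                add("diffusion", f"unknown species {col!r} in diffusion entry D[{row}][{col}]")
                continue
            uses_space = True
            check_expr(
                f"diffusion.{row}.{col}", src, kin_syms,
                forbid_derivs=True, context="diffusivities",
            )

    # kinetics
    for sp, src in cfg.kinetics.items():
        if sp not in names:
            add("kinetics", f"unknown species {sp!r}")
            continue
        if sp not in cfg.differential_species():
            add("kinetics", f"kinetics given for non-differential species {sp!r}")
            continue
        e = check_expr(f"kinetics.{sp}", src, kin_syms)
        if e is not None and any(derivative_token(s, names) for s in e.free_symbols):
            uses_space = True

    # algebraic definitions
    for s in cfg.algebraic_species():
        if s.algebraic_rhs:
            e = check_expr(f"species.{s.name}.algebraic_rhs", s.algebraic_rhs, kin_syms)
            if e is not None and any(derivative_token(x, names) for x in e.free_symbols):
                uses_space = True
    try:
        algebraic_order(cfg)
    except AlgebraicCycleError as err:
        add("species", str(err))

    # boundary conditions
    for sp, per in cfg.boundary_conditions.items():
        if sp not in names:
            add("boundary_conditions", f"unknown species {sp!r}")
            continue
        for edge, bc in per.items():
            if edge not in cfg.edges():
                add(f"boundary_conditions.{sp}", f"unknown edge {edge!r} for this dimension")
                continue
            if bc.kind not in BC_KINDS:
                add(f"boundary_conditions.{sp}.{edge}", f"unknown kind {bc.kind!r}")
                continue
            if bc.kind != "periodic":
                check_expr(
                    f"boundary_conditions.{sp}.{edge}", bc.value, base_syms,
                )
    # periodic pairing (defaults are periodic, so only explicit mismatches matter)
    axes = [("left", "right")] + ([("bottom", "top")] if dom.dimension == 2 else [])
    for sp in names:
        for a, b in axes:
            ka, kb = cfg.bc(sp, a).kind, cfg.bc(sp, b).kind
            if (ka == "periodic") != (kb == "periodic"):
                add(
                    f"boundary_conditions.{sp}",
                    f"periodic must be paired on both {a}/{b} edges (got {ka}/{kb})",
                )

    # indicator
    if dom.indicator is not None:
        ind_syms = {"x"} | ({"y"} if dom.dimension == 2 else set()) | set(cfg.params)
        ind_syms |= set(cfg.images) & set(IMAGE_FUNCTIONS)
        check_expr("domain.indicator", dom.indicator, ind_syms)

    # initial conditions (coordinates, params, images, seeded noise symbol)
    ic_syms = (
        {"x"} | ({"y"} if dom.dimension == 2 else set())
        | set(cfg.params) | (set(cfg.images) & set(IMAGE_FUNCTIONS)) | {"rand"}
    )
    for sp in cfg.differential_species():
        if sp not in cfg.initial_conditions:
            add("initial_conditions", f"missing initial condition for {sp!r}")
    for sp, src in cfg.initial_conditions.items():
        if sp not in names:
            add("initial_conditions", f"unknown species {sp!r}")
            continue
        if sp not in cfg.differential_species():
            add("initial_conditions", f"initial condition given for algebraic species {sp!r}")
            continue
        check_expr(f"initial_conditions.{sp}", src, ic_syms)

    # views
    for i, v in enumerate(cfg.views):
        check_expr(f"views[{i}].expression", v.expression, kin_syms)
        if v.scaling != "adaptive":
            ok = (
                isinstance(v.scaling, (list, tuple))
                and len(v.scaling) == 2
                and all(isinstance(s, (int, float)) for s in v.scaling)
            )
            if not ok:
                add(f"views[{i}].scaling", "must be 'adaptive' or [vmin, vmax]")

    # brush events
    for i, b in enumerate(cfg.brush_events):
        if b.species not in names:
            add(f"brush_events[{i}]", f"unknown species {b.species!r}")
        if b.shape not in ("disc", "gaussian"):
            add(f"brush_events[{i}]", f"unknown shape {b.shape!r}")
        if b.mode not in ("set", "add"):
            add(f"brush_events[{i}]", f"unknown mode {b.mode!r}")
        cx = b.center[0]
        inside = 0 <= cx <= dom.Lx
        if dom.dimension == 2:
            inside = inside and len(b.center) > 1 and 0 <= b.center[1] <= (dom.Ly or 0)
        if not inside:
            add(f"brush_events[{i}]", "centre lies outside the domain")

    # images
    for key in cfg.images:
        if key not in IMAGE_FUNCTIONS:
            add("images", f"unknown image slot {key!r} (use I_S or I_T)")

    # param ranges (slider metadata)
    for p, rng in cfg.param_ranges.items():
        if p not in cfg.params:
            add("param_ranges", f"range given for unknown parameter {p!r}")
        elif len(rng) != 2 or rng[0] > rng[1]:
            add("param_ranges", f"{p}: range must be [lo, hi] with lo <= hi")

    # stencil feasibility: axes along which operators act need >= 3 nodes
    if uses_space and num.dx > 0 and dom.Lx and dom.Lx > 0:
        nx = int(dom.Lx / num.dx)
        if nx < 3:
            add("numerics.dx", f"only {nx} node(s) along x; spatial stencils need >= 3")
        if dom.dimension == 2 and dom.Ly and dom.Ly > 0:
            ny = int(dom.Ly / num.dx)
            if ny < 3:
                add("numerics.dx", f"only {ny} node(s) along y; spatial stencils need >= 3")

    return out
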