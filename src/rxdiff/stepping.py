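"""Explicit fixed-step time integration and the run loop.

Four schemes advance the method-of-lines ODE system u' = R(u, t):

* ``forward_euler``   u_{n+1} = u_n + dt R(u_n, t_n)                (order 1)
* ``midpoint``        u_{n+1} = u_n + dt R(u_n + dt/2 R(u_n), t_n + dt/2)  (order 2)
* ``adams_bashforth2``  u_{n+1} = u_n + dt (3/2 R_n - 1/2 R_{n-1}); the
  first step (no history) is delegated to the midpoint method so the scheme
  stays second order                                                 (order 2)
* ``rk4``             the classical four-stage tableau               (order 4)

Algebraic species are recomputed at every stage evaluation (inside the RHS)
and after the final stage; Dirichlet nodes are re-pinned at the new time.
dt is never adapted: a stability advisory is logged but not enforced.
Blow-up (any non-finite value) is detected at step boundaries and raised as
:class:`BlowUpError` by the run loop.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .model import SimulationConfig
from .operators import System

__all__ = [
    "FieldState",
    "Stepper",
    "Checkpoint",
    "RunResult",
    "BlowUpError",
    "step",
    "detect_blowup",
    "apply_brush",
    "run",
    "resume",
    "config_hash",
]

log = logging.getLogger("rxdiff")


class BlowUpError(RuntimeError):
    """Solution blew up (non-finite values)."""

    def __init__(self, t, step_index, partial=None):
        self.t = t
        self.step_index = step_index
        self.partial = partial
        super().__init__(f"solution blew up at t={t:g} (step {step_index})")


@dataclass
class FieldState:
    """All species fields on the grid plus the simulation clock."""

    fields: dict  # name -> (ny, nx) float array
    t: float = 0.0
    step_index: int = 0

    def copy(self) -> "FieldState":
        return FieldState(
            fields={k: v.copy() for k, v in self.fields.items()},
            t=self.t,
            step_index=self.step_index,
        )


@dataclass
class Checkpoint:
    state: FieldState
    config_hash: str
    prev_rhs: dict | None = None  # Adams-Bashforth history, needed for bit-exact resume


@dataclass
class RunResult:
    state: FieldState
    frames: list = field(default_factory=list)  # [FieldState]
    checkpoints: list = field(default_factory=list)  # [Checkpoint]
    events: list = field(default_factory=list)  # log of brush/scheme/blow-up events


def config_hash(cfg: SimulationConfig) -> str:
    doc = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


class Stepper:
    """One explicit scheme plus its history (AB2 keeps the previous RHS).

    History is cleared whenever dt or the scheme changes mid-run.
    """

    def __init__(self, scheme: str):
        self.scheme = scheme
        self.prev_rhs: dict | None = None
        self._dt: float | None = None

    def reset(self):
        self.prev_rhs = None
        self._dt = None

    def step(self, system: System, state: FieldState, dt: float) -> FieldState:
        if self._dt is not None and dt != self._dt:
            self.reset()
        self._dt = dt
        f, t = state.fields, state.t
        diff = system.differential

        def advance(base, rates, h):
            out = dict(base)
            for sp in diff:
                out[sp] = base[sp] + h * rates[sp]
            return out

        if self.scheme == "forward_euler":
            r = system.rhs(f, t)
            new = advance(f, r, dt)
        elif self.scheme == "midpoint":
            k1 = system.rhs(f, t)
            mid = advance(f, k1, dt / 2.0)
            k2 = system.rhs(mid, t + dt / 2.0)
            new = advance(f, k2, dt)
        elif self.scheme == "adams_bashforth2":
            r = system.rhs(f, t)
            if self.prev_rhs is None:
                mid = advance(f, r, dt / 2.0)
                k2 = system.rhs(mid, t + dt / 2.0)
                new = advance(f, k2, dt)
            else:
                comb = {
                    sp: 1.5 * r[sp] - 0.5 * self.prev_rhs[sp] for sp in diff
                }
                new = advance(f, comb, dt)
            self.prev_rhs = r
        elif self.scheme == "rk4":
            k1 = system.rhs(f, t)
            k2 = system.rhs(advance(f, k1, dt / 2.0), t + dt / 2.0)
            k3 = system.rhs(advance(f, k2, dt / 2.0), t + dt / 2.0)
            k4 = system.rhs(advance(f, k3, dt), t + dt)
            comb = {
                sp: (k1[sp] + 2.0 * (k2[sp] + k3[sp]) + k4[sp]) / 6.0 for sp in diff
            }
            new = advance(f, comb, dt)
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

        t_new = t + dt
        system.prepare(new, t_new)
        return FieldState(fields=new, t=t_new, step_index=state.step_index + 1)


def step(state: FieldState, cfg: SimulationConfig, stepper: Stepper, dt: float,
         system: System | None = None) -> FieldState:
    """Advance one step (module-level convenience wrapper)."""
    return stepper.step(system or System(cfg), state, dt)


def detect_blowup(state: FieldState) -> bool:
    """True iff any species field contains a non-finite value."""
    return any(not np.isfinite(v).all() for v in state.fields.values())


def apply_brush(state: FieldState, ev, grid) -> FieldState:
    """Paint on a species field: a hard disc (set or add) or an additive
    gaussian bump value * exp(-r^2 / 2 sigma^2)."""
    if ev.species not in state.fields:
        raise KeyError(f"unknown species {ev.species!r}")
    out = state.copy()
    cx = ev.center[0]
    cy = ev.center[1] if len(ev.center) > 1 else grid.Ly / 2.0
    r2 = (grid.X - cx) ** 2 + ((grid.Y - cy) ** 2 if grid.dimension == 2 else 0.0)
    F = out.fields[ev.species]
    if ev.shape == "disc":
        hit = r2 <= ev.radius**2
        if ev.mode == "set":
            F[hit] = ev.value
        else:
            F[hit] += ev.value
    elif ev.shape == "gaussian":
        bump = ev.value * np.exp(-r2 / (2.0 * ev.radius**2))
        if ev.mode == "set":
            F[...] = bump
        else:
            F += bump
    else:
        raise ValueError(f"unknown brush shape {ev.shape!r}")
    return out


def _segments(cfg) -> list:
    segs = cfg.numerics.scheme_segments
    if not segs:
        return [(0.0, cfg.numerics.scheme)]
    out = [tuple(s) for s in segs]
    if out[0][0] > 0.0:
        out.insert(0, (0.0, cfg.numerics.scheme))
    return out


def _scheme_at(segments, t):
    current = segments[0][1]
    for t0, sch in segments:
        if t >= t0 - 1e-15:
            current = sch
    return current


def run(
    cfg: SimulationConfig,
    t_end: float,
    callbacks: list | None = None,
    checkpoint_times: list | None = None,
    system: System | None = None,
    initial_state: FieldState | None = None,
    stepper: Stepper | None = None,
    capture_frames: bool = True,
) -> RunResult:
    """Run from the configured initial conditions until t >= t_end.

    Frames are captured every ``numerics.steps_per_frame`` steps (plus the
    initial state); brush events fire once their time is reached; the
    timestepping scheme may switch between declared time segments.  The run
    is deterministic given the config (including its seed).  Raises
    :class:`BlowUpError`, carrying the partial result, when any field goes
    non-finite.
    """
    system = system or System(cfg)
    dt = cfg.numerics.dt
    spf = cfg.numerics.steps_per_frame
    segments = _segments(cfg)

    if initial_state is None:
        state = FieldState(fields=system.initial_fields(), t=0.0, step_index=0)
    else:
        state = initial_state.copy()
        system.prepare(state.fields, state.t)

    result = RunResult(state=state)
    if capture_frames:
        result.frames.append(state.copy())

    adv = system.stable_dt_advisory(state.fields)
    if adv is not None and dt > adv:
        log.warning(
            "dt=%g exceeds the explicit-diffusion stability advisory %g; "
            "expect possible blow-up", dt, adv,
        )

    pending_brush = sorted(
        (b for b in cfg.brush_events if b.time >= state.t), key=lambda b: b.time
    )
    pending_ckpt = sorted(checkpoint_times or [])
    stepper = stepper or Stepper(_scheme_at(segments, state.t))

    while state.t < t_end - 1e-12 * max(1.0, abs(t_end)):
        sch = _scheme_at(segments, state.t)
        if sch != stepper.scheme:
            result.events.append(("scheme", state.t, sch))
            stepper.scheme = sch
            stepper.reset()
        while pending_brush and pending_brush[0].time <= state.t + 1e-15:
            ev = pending_brush.pop(0)
            state = apply_brush(state, ev, system.grid)
            system.prepare(state.fields, state.t)
            stepper.reset()
            result.events.append(("brush", state.t, ev.species))

        state = stepper.step(system, state, dt)

        if detect_blowup(state):
            result.state = state
            result.events.append(("blowup", state.t, None))
            raise BlowUpError(state.t, state.step_index, partial=result)

        if capture_frames and state.step_index % spf == 0:
            result.frames.append(state.copy())
        while pending_ckpt and state.t >= pending_ckpt[0] - 1e-12:
            pending_ckpt.pop(0)
            result.checkpoints.append(
                Checkpoint(
                    state=state.copy(),
                    config_hash=config_hash(cfg),
                    prev_rhs=copy.deepcopy(stepper.prev_rhs),
                )
            )
        if callbacks:
            for cb in callbacks:
                cb(state)

    result.state = state
    return result


def resume(checkpoint: Checkpoint, cfg: SimulationConfig, t_end: float,
           system: System | None = None, capture_frames: bool = True) -> RunResult:
    """Continue a run from a checkpoint; bit-identical to never stopping."""
    if checkpoint.config_hash != config_hash(cfg):
        raise ValueError("checkpoint was taken under a different configuration")
    segments = _segments(cfg)
    stepper = Stepper(_scheme_at(segments, checkpoint.state.t))
    stepper.prev_rhs = copy.deepcopy(checkpoint.prev_rhs)
    stepper._dt = cfg.numerics.dt if checkpoint.prev_rhs is not None else None
    return run(
        cfg,
        t_end,
        system=system,
        initial_state=checkpoint.state,
        stepper=stepper,
        capture_frames=capture_frames,
    )
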