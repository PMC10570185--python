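# Configuration file format

A simulation is one JSON object.  Unknown keys are rejected by name at any
level.  All formulas are strings in the grammar of `expressions.md`.
Presets in `src/rxdiff/presets/data/` use exactly this schema (wrapped with
`title`/`provenance` metadata), so they double as worked examples.

```jsonc
{
  "title": "string",                       // optional, free text
  "species": [                             // at least one differential
    {"name": "u", "role": "differential", "algebraic_rhs": null},
    {"name": "v", "role": "algebraic",    "algebraic_rhs": "u_x"}
  ],
  "diffusion": {                           // row: equation, col: gradient of
    "u": {"u": "D", "v": "-chi*u"}         // du/dt += div(D_uv grad v) ...
  },                                       // absent entries are zero
  "kinetics": {"u": "u*(1 - u)"},          // f_i per differential species
  "boundary_conditions": {                 // default: periodic everywhere
    "u": {
      "left":  {"kind": "neumann",   "value": "0"},
      "right": {"kind": "dirichlet", "value": "sin(t)"},
      "bottom": {"kind": "periodic", "value": "0"},   // must pair with top
      "top":    {"kind": "periodic", "value": "0"}
    }
  },
  "domain": {
    "dimension": 2,                        // 1 or 2
    "Lx": 1.0, "Ly": 1.0,                  // Ly ignored in 1D
    "indicator": "heaviside(0.25 - (x-0.5)^2 - (y-0.5)^2)"  // or null
  },
  "numerics": {
    "dx": 0.01,                            // one step size for both axes
    "dt": 1e-5,
    "scheme": "forward_euler",             // | adams_bashforth2 | midpoint | rk4
    "steps_per_frame": 100,
    "scheme_segments": [[0.0, "forward_euler"], [1.0, "rk4"]]  // or null
  },
  "params": {"D": 1.0, "chi": 5.0},
  "param_ranges": {"chi": [0.0, 10.0]},    // optional slider metadata only
  "initial_conditions": {"u": "1 + 0.1*(rand - 0.5)"},
  "views": [
    {"name": "cells", "expression": "u", "colormap": "viridis",
     "scaling": "adaptive",                // or [vmin, vmax]
     "colorbar": false}
  ],
  "brush_events": [
    {"time": 0.5, "species": "u", "shape": "disc",   // | gaussian
     "center": [0.5, 0.5], "radius": 0.1, "value": 1.0, "mode": "set"}
  ],
  "images": {"I_S": "path/to/photo.png"},  // paths, never pixel data
  "seed": 0                                // drives the "rand" IC symbol
}
```

Boundary `value` semantics: for `dirichlet` the imposed boundary value; for
`neumann`/`robin` the outward-normal derivative `g` (`robin` simply allows
`g` to reference the species itself).  Periodic conditions must be declared
on both edges of an axis.

Serialization profiles: `full` round-trips every field bit-identically;
`share` (the shareable description of a simulation given its specified
initial conditions) omits `brush_events`.
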