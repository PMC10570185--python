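{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "u": "1",
        "v": "-chi*u"
      },
      "v": {
        "v": "D"
      }
    },
    "domain": {
      "Lx": 10.0,
      "Ly": 10.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "1 + 0.1*(rand - 0.5)",
      "v": "1"
    },
    "kinetics": {
      "u": "u*(1 - u)",
      "v": "u - v"
    },
    "numerics": {
      "dt": 0.0002,
      "dx": 0.1,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 500
    },
    "param_ranges": {
      "chi": [
        0.0,
        10.0
      ]
    },
    "params": {
      "D": 1.0,
      "chi": 5.0
    },
    "seed": 7,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      },
      {
        "algebraic_rhs": null,
        "name": "v",
        "role": "differential"
      }
    ],
    "title": "Keller-Segel chemotaxis (minimal model with logistic growth)",
    "views": [
      {
        "colorbar": false,
        "colormap": "flame",
        "expression": "u",
        "name": "cells",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "u_t = Lap(u) - div(chi u grad v) + u(1-u); v_t = D Lap(v) + u - v. Chemotaxis enters through the cross-diffusion slot D_uv = -chi*u.",
  "title": "Keller-Segel chemotaxis (minimal model with logistic growth)"
}
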