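{
  "config": {
    "boundary_conditions": {
      "u": {
        "left": {
          "kind": "neumann",
          "value": "0"
        },
        "right": {
          "kind": "neumann",
          "value": "0"
        }
      }
    },
    "brush_events": [],
    "diffusion": {
      "u": {
        "u": "D"
      }
    },
    "domain": {
      "Lx": 100.0,
      "Ly": null,
      "dimension": 1,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "heaviside(5 - x)"
    },
    "kinetics": {
      "u": "r*u*(1 - u)"
    },
    "numerics": {
      "dt": 0.01,
      "dx": 0.25,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 500
    },
    "param_ranges": {},
    "params": {
      "D": 1.0,
      "r": 1.0
    },
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      }
    ],
    "title": "Fisher-KPP travelling wave",
    "views": [
      {
        "colorbar": false,
        "colormap": "viridis",
        "expression": "u",
        "name": "u",
        "scaling": [
          0.0,
          1.1
        ]
      }
    ]
  },
  "provenance": "u_t = D u_xx + r u (1 - u); pulled front invading u = 0 at speed 2 sqrt(r D).",
  "title": "Fisher-KPP travelling wave"
}
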