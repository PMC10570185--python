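{
  "config": {
    "boundary_conditions": {
      "u": {
        "bottom": {
          "kind": "neumann",
          "value": "0"
        },
        "left": {
          "kind": "neumann",
          "value": "0"
        },
        "right": {
          "kind": "neumann",
          "value": "0"
        },
        "top": {
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
      "Lx": 1.0,
      "Ly": 1.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "exp(-((x-0.5)^2 + (y-0.5)^2)/0.01)"
    },
    "kinetics": {
      "u": "0"
    },
    "numerics": {
      "dt": 5e-05,
      "dx": 0.02,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 200
    },
    "param_ranges": {},
    "params": {
      "D": 1.0
    },
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      }
    ],
    "title": "Heat equation (2D, insulated walls)",
    "views": [
      {
        "colorbar": false,
        "colormap": "flame",
        "expression": "u",
        "name": "u",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "Classical linear diffusion u_t = D Lap(u); textbook separation-of-variables system.",
  "title": "Heat equation (2D, insulated walls)"
}
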