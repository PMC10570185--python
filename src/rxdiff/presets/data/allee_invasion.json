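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
      "u": "heaviside(10 - abs(x - 50))"
    },
    "kinetics": {
      "u": "u*(u - a)*(1 - u)"
    },
    "numerics": {
      "dt": 0.01,
      "dx": 0.25,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 500
    },
    "param_ranges": {
      "a": [
        0.0,
        0.5
      ]
    },
    "params": {
      "D": 1.0,
      "a": 0.25
    },
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      }
    ],
    "title": "Bistable invasion with a strong Allee effect",
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
  "provenance": "u_t = D u_xx + u (u - a)(1 - u), a = 0.25; persistence of a compact introduction depends on its mass and shape.",
  "title": "Bistable invasion with a strong Allee effect"
}
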