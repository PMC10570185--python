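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
      },
      "v": {
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
      "v": {
        "u": "0.25 + 0.75*heaviside(x - 0.5)"
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
      "u": "exp(-((x-0.3)^2 + (y-0.5)^2)/0.002)",
      "v": "0"
    },
    "kinetics": {
      "u": "v",
      "v": "0"
    },
    "numerics": {
      "dt": 0.004,
      "dx": 0.01,
      "scheme": "rk4",
      "scheme_segments": null,
      "steps_per_frame": 25
    },
    "param_ranges": {},
    "params": {},
    "seed": 0,
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
    "title": "Inhomogeneous wave equation",
    "views": [
      {
        "colorbar": false,
        "colormap": "diverging",
        "expression": "u",
        "name": "u",
        "scaling": [
          -0.5,
          0.5
        ]
      }
    ]
  },
  "provenance": "u_tt = div(f(x,y) grad u) recast as u_t = v, v_t = div(f grad u); piecewise-constant squared wave speed f jumping at x = Lx/2.",
  "title": "Inhomogeneous wave equation"
}
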