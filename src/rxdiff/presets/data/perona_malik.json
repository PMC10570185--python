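{
  "config": {
    "boundary_conditions": {
      "s": {
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
        "u": "1/(1 + s/K^2)"
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
      "u": "0.25 + 0.5*heaviside(x - 0.5) + 0.2*(rand - 0.5)"
    },
    "kinetics": {
      "u": "0"
    },
    "numerics": {
      "dt": 2e-05,
      "dx": 0.015625,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 25
    },
    "param_ranges": {
      "K": [
        1.0,
        60.0
      ]
    },
    "params": {
      "K": 15.0
    },
    "seed": 23,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      },
      {
        "algebraic_rhs": "u_x^2 + u_y^2",
        "name": "s",
        "role": "algebraic"
      }
    ],
    "title": "Perona-Malik edge-preserving denoising",
    "views": [
      {
        "colorbar": false,
        "colormap": "viridis",
        "expression": "u",
        "name": "image",
        "scaling": [
          0.0,
          1.0
        ]
      }
    ]
  },
  "provenance": "u_t = div(g(|grad u|^2) grad u), g(s) = 1/(1 + s/K^2), via the algebraic species s = u_x^2 + u_y^2 feeding the diffusivity slot; noisy two-level step initial data.",
  "title": "Perona-Malik edge-preserving denoising"
}
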