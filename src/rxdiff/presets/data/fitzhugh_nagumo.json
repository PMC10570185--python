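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
      "u": {
        "u": "Du"
      }
    },
    "domain": {
      "Lx": 100.0,
      "Ly": 100.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "-1.2 + 2.4*heaviside(10 - x)*heaviside(50 - y)",
      "v": "-0.625 + 0.8*heaviside(y - 50)*heaviside(20 - x)"
    },
    "kinetics": {
      "u": "u - u^3/3 - v",
      "v": "eps*(u + beta - gamma*v)"
    },
    "numerics": {
      "dt": 0.02,
      "dx": 0.5,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 250
    },
    "param_ranges": {},
    "params": {
      "Du": 1.0,
      "beta": 0.7,
      "eps": 0.1,
      "gamma": 0.8
    },
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
    "title": "FitzHugh-Nagumo excitable waves",
    "views": [
      {
        "colorbar": false,
        "colormap": "diverging",
        "expression": "u",
        "name": "u",
        "scaling": [
          -2.2,
          2.2
        ]
      }
    ]
  },
  "provenance": "u_t = Du Lap(u) + u - u^3/3 - v; v_t = eps (u + beta - gamma v). beta = 0.7, gamma = 0.8, eps = 0.1; broken-front initial data spawns a spiral.",
  "title": "FitzHugh-Nagumo excitable waves"
}
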