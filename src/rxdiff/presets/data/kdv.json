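{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {},
    "domain": {
      "Lx": 50.0,
      "Ly": null,
      "dimension": 1,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "phi": "(c/2)*(1 - tanh(sqrt(c)/2*((x - x0)))^2)"
    },
    "kinetics": {
      "phi": "-v_xx - 6*v*phi"
    },
    "numerics": {
      "dt": 0.00048521557689715076,
      "dx": 0.09765625,
      "scheme": "rk4",
      "scheme_segments": null,
      "steps_per_frame": 2000
    },
    "param_ranges": {},
    "params": {
      "c": 4.0,
      "x0": 12.5
    },
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "phi",
        "role": "differential"
      },
      {
        "algebraic_rhs": "phi_x",
        "name": "v",
        "role": "algebraic"
      }
    ],
    "title": "KdV single soliton",
    "views": [
      {
        "colorbar": false,
        "colormap": "viridis",
        "expression": "phi",
        "name": "phi",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "phi_t = -phi_xxx - 6 phi phi_x posed as phi_t = -v_xx - 6 v phi with algebraic v = phi_x; single sech^2 soliton of speed c on a periodic interval.",
  "title": "Korteweg-de Vries soliton"
}
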