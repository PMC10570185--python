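{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "w": "1"
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
      "u": "0.1*(rand - 0.5)"
    },
    "kinetics": {
      "u": "0"
    },
    "numerics": {
      "dt": 2e-06,
      "dx": 0.02,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 1000
    },
    "param_ranges": {},
    "params": {
      "gamma": 0.001
    },
    "seed": 5,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      },
      {
        "algebraic_rhs": "u^3 - u - gamma*(u_xx + u_yy)",
        "name": "w",
        "role": "algebraic"
      }
    ],
    "title": "Cahn-Hilliard coarsening",
    "views": [
      {
        "colorbar": false,
        "colormap": "diverging",
        "expression": "u",
        "name": "u",
        "scaling": [
          -1.0,
          1.0
        ]
      }
    ]
  },
  "provenance": "u_t = Lap(u^3 - u - gamma Lap u) with algebraic chemical potential w = u^3 - u - gamma Lap(u); spinodal decomposition from small noise.",
  "title": "Cahn-Hilliard coarsening"
}
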