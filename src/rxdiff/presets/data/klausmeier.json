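{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "u": "D"
      }
    },
    "domain": {
      "Lx": 50.0,
      "Ly": null,
      "dimension": 1,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "1 + 0.5*(rand - 0.5)",
      "w": "1 + 0.1*(rand - 0.5)"
    },
    "kinetics": {
      "u": "w*u^2 - m*u",
      "w": "a - w - w*u^2 + nu*w_x_f"
    },
    "numerics": {
      "dt": 0.002,
      "dx": 0.2,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 1000
    },
    "param_ranges": {},
    "params": {
      "D": 1.0,
      "a": 2.0,
      "m": 0.45,
      "nu": 20.0
    },
    "seed": 13,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "w",
        "role": "differential"
      },
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      }
    ],
    "title": "Klausmeier vegetation stripes on a hillside",
    "views": [
      {
        "colorbar": false,
        "colormap": "viridis",
        "expression": "u",
        "name": "vegetation",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "w_t = a - w - w u^2 + nu w_x (downhill water advection, forward-upwind); u_t = D u_xx + w u^2 - m u. a = 2, m = 0.45; advection scaled to the domain.",
  "title": "Klausmeier vegetation stripes on a hillside"
}
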