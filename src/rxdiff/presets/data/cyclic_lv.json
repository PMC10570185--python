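{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "u": "D"
      },
      "v": {
        "v": "D"
      },
      "w": {
        "w": "D"
      }
    },
    "domain": {
      "Lx": 50.0,
      "Ly": 50.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "0.3 + 0.3*(rand - 0.5)",
      "v": "0.3 + 0.3*(rand - 0.5)",
      "w": "0.3 + 0.3*(rand - 0.5)"
    },
    "kinetics": {
      "u": "u*(1 - u - alpha*v - beta*w)",
      "v": "v*(1 - v - alpha*w - beta*u)",
      "w": "w*(1 - w - alpha*u - beta*v)"
    },
    "numerics": {
      "dt": 0.05,
      "dx": 0.5,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 200
    },
    "param_ranges": {},
    "params": {
      "D": 0.5,
      "alpha": 0.8,
      "beta": 1.9
    },
    "seed": 17,
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
      },
      {
        "algebraic_rhs": null,
        "name": "w",
        "role": "differential"
      }
    ],
    "title": "Cyclic (rock-paper-scissors) Lotka-Volterra spirals",
    "views": [
      {
        "colorbar": false,
        "colormap": "diverging",
        "expression": "u - v",
        "name": "u - v",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "May-Leonard competition: each species obeys s_t = D Lap(s) + s (1 - s - alpha s_next - beta s_prev) with alpha = 0.8, beta = 1.9 (spiral-forming cyclic dominance).",
  "title": "Cyclic (rock-paper-scissors) Lotka-Volterra spirals"
}
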