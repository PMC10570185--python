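{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "u": "Du"
      },
      "v": {
        "v": "Dv"
      }
    },
    "domain": {
      "Lx": 2.5,
      "Ly": 2.5,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "1 - 0.5*heaviside(0.1 - abs(x - 1.25))*heaviside(0.1 - abs(y - 1.25)) + 0.02*(rand - 0.5)",
      "v": "0.25*heaviside(0.1 - abs(x - 1.25))*heaviside(0.1 - abs(y - 1.25)) + 0.02*(rand - 0.5)*heaviside(0.15 - abs(x - 1.25))"
    },
    "kinetics": {
      "u": "-u*v^2 + F*(1 - u)",
      "v": "u*v^2 - (F + k)*v"
    },
    "numerics": {
      "dt": 0.5,
      "dx": 0.01,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 1000
    },
    "param_ranges": {
      "F": [
        0.0,
        0.08
      ],
      "k": [
        0.03,
        0.07
      ]
    },
    "params": {
      "Du": 2e-05,
      "Dv": 1e-05,
      "F": 0.037,
      "k": 0.06
    },
    "seed": 11,
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
    "title": "Gray-Scott model (spot-forming regime)",
    "views": [
      {
        "colorbar": false,
        "colormap": "flame",
        "expression": "v",
        "name": "v",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "Cubic autocatalysis u_t = Du Lap(u) - u v^2 + F(1-u), v_t = Dv Lap(v) + u v^2 - (F+k) v; Pearson's parameter map, F = 0.037, k = 0.06 (spots).",
  "title": "Gray-Scott model (spot-forming regime)"
}
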