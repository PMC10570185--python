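{
  "config": {
    "boundary_conditions": {},
    "brush_events": [],
    "diffusion": {
      "u": {
        "w": "-1"
      }
    },
    "domain": {
      "Lx": 40.0,
      "Ly": 40.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "1.2*exp(-((x-20)^2 + (y-20)^2)/4)"
    },
    "kinetics": {
      "u": "(r - 1)*u - 2*w + s*u^2 - u^3"
    },
    "numerics": {
      "dt": 0.0004,
      "dx": 0.4,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 1000
    },
    "param_ranges": {
      "r": [
        -0.4,
        0.0
      ]
    },
    "params": {
      "r": -0.28,
      "s": 1.8
    },
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      },
      {
        "algebraic_rhs": "u_xx + u_yy",
        "name": "w",
        "role": "algebraic"
      }
    ],
    "title": "Swift-Hohenberg equation (localised states)",
    "views": [
      {
        "colorbar": false,
        "colormap": "diverging",
        "expression": "u",
        "name": "u",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "u_t = r u - (1 + Lap)^2 u + s u^2 - u^3 with algebraic w = Lap(u): u_t = (r-1) u - 2 w - Lap(w) + s u^2 - u^3. Quadratic-cubic branch (r = -0.28, s = 1.8) supports localised patches.",
  "title": "Swift-Hohenberg equation (localised states)"
}
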