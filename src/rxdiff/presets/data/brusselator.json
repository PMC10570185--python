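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
      "Lx": 50.0,
      "Ly": 50.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "2 + 0.1*(rand - 0.5)",
      "v": "1.5 + 0.1*(rand - 0.5)"
    },
    "kinetics": {
      "u": "a - (b + 1)*u + u^2*v",
      "v": "b*u - u^2*v"
    },
    "numerics": {
      "dt": 0.002,
      "dx": 0.5,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 500
    },
    "param_ranges": {
      "b": [
        1.0,
        5.0
      ]
    },
    "params": {
      "Du": 1.0,
      "Dv": 10.0,
      "a": 2.0,
      "b": 3.0
    },
    "seed": 29,
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
    "title": "Brusselator Turing patterns",
    "views": [
      {
        "colorbar": false,
        "colormap": "flame",
        "expression": "u",
        "name": "u",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "u_t = Du Lap(u) + a - (b+1) u + u^2 v; v_t = Dv Lap(v) + b u - u^2 v. a = 2, b = 3, Du = 1, Dv = 10 is Turing-unstable about (a, b/a).",
  "title": "Brusselator Turing patterns"
}
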