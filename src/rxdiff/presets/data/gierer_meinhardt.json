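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
      "Lx": 40.0,
      "Ly": 40.0,
      "dimension": 2,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "2*(1 + 0.1*cos(2*pi*3*y/40)) + 0.02*(rand - 0.5)",
      "v": "4"
    },
    "kinetics": {
      "u": "u^2/v - b*u",
      "v": "u^2 - v"
    },
    "numerics": {
      "dt": 0.01,
      "dx": 0.4,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 500
    },
    "param_ranges": {},
    "params": {
      "Du": 0.02,
      "Dv": 1.0,
      "b": 0.5
    },
    "seed": 3,
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
    "title": "Gierer-Meinhardt activator-inhibitor (stripe initial data)",
    "views": [
      {
        "colorbar": false,
        "colormap": "viridis",
        "expression": "u",
        "name": "activator",
        "scaling": "adaptive"
      }
    ]
  },
  "provenance": "u_t = Du Lap(u) + u^2/v - b u; v_t = Dv Lap(v) + u^2 - v. b = 0.5, Du = 0.02, Dv = 1 puts the homogeneous state (2, 4) inside the Turing-unstable band; stripe initial data breaks up into spots.",
  "title": "Gierer-Meinhardt activator-inhibitor (stripe initial data)"
}
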