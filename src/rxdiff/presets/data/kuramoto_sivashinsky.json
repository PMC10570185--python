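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
      "Lx": 64.0,
      "Ly": null,
      "dimension": 1,
      "indicator": null
    },
    "images": {},
    "initial_conditions": {
      "u": "cos(2*pi*x/64) + 0.1*cos(4*pi*x/64)"
    },
    "kinetics": {
      "u": "-w - u*u_x"
    },
    "numerics": {
      "dt": 0.0002,
      "dx": 0.25,
      "scheme": "forward_euler",
      "scheme_segments": null,
      "steps_per_frame": 5000
    },
    "param_ranges": {},
    "params": {},
    "seed": 0,
    "species": [
      {
        "algebraic_rhs": null,
        "name": "u",
        "role": "differential"
      },
      {
        "algebraic_rhs": "u_xx",
        "name": "w",
        "role": "algebraic"
      }
    ],
    "title": "Kuramoto-Sivashinsky spatiotemporal chaos",
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
  "provenance": "u_t = -u u_x - u_xx - u_xxxx with algebraic w = u_xx: u_t = -w - Lap(w) - u u_x on a periodic interval of length 64.",
  "title": "Kuramoto-Sivashinsky spatiotemporal chaos"
}
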