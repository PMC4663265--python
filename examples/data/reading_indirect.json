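{
  "mode": "indirect",
  "predictor_names": [
    "attitude",
    "online"
  ],
  "outcome_name": "reading",
  "classes": [
    {
      "weight": 0.606,
      "kappa": [
        2.273,
        3.274
      ],
      "phi": [
        [
          0.272,
          0.063
        ],
        [
          0.063,
          0.318
        ]
      ],
      "alpha": -0.157,
      "gamma_lin": [
        0.025,
        0.45
      ],
      "gamma_quad": [
        [
          0.017,
          0.01
        ],
        [
          0.01,
          -0.063
        ]
      ],
      "psi": 0.027
    },
    {
      "weight": 0.394,
      "kappa": [
        3.333,
        3.498
      ],
      "phi": [
        [
          0.14,
          0.017
        ],
        [
          0.017,
          0.177
        ]
      ],
      "alpha": -0.157,
      "gamma_lin": [
        0.025,
        0.45
      ],
      "gamma_quad": [
        [
          0.017,
          0.01
        ],
        [
          0.01,
          -0.063
        ]
      ],
      "psi": 0.027
    }
  ]
}
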