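{
  "mode": "direct",
  "predictor_names": [
    "attitude",
    "online"
  ],
  "outcome_name": "reading",
  "classes": [
    {
      "weight": 0.626,
      "kappa": [
        2.341,
        3.272
      ],
      "phi": [
        [
          0.344,
          0.063
        ],
        [
          0.063,
          0.302
        ]
      ],
      "alpha": -0.147,
      "gamma_lin": [
        0.309,
        0.305
      ],
      "gamma_quad": [
        [
          -0.029,
          -0.042
        ],
        [
          -0.042,
          -0.026
        ]
      ],
      "psi": 0.028
    },
    {
      "weight": 0.374,
      "kappa": [
        3.276,
        3.514
      ],
      "phi": [
        [
          0.188,
          0.016
        ],
        [
          0.016,
          0.149
        ]
      ],
      "alpha": 1.471,
      "gamma_lin": [
        -0.045,
        -0.252
      ],
      "gamma_quad": [
        [
          0.009,
          0.009
        ],
        [
          0.009,
          0.036
        ]
      ],
      "psi": 0.002
    }
  ]
}
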