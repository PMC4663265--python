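{
  "mode": "multigroup",
  "predictor_names": [
    "attitude",
    "online"
  ],
  "outcome_name": "reading",
  "classes": [
    {
      "weight": 0.5,
      "kappa": [
        2.875,
        3.409
      ],
      "phi": [
        [
          0.479,
          0.055
        ],
        [
          0.055,
          0.256
        ]
      ],
      "alpha": -0.525,
      "gamma_lin": [
        -0.037,
        0.721
      ],
      "gamma_quad": [
        [
          0.02,
          0.021
        ],
        [
          0.021,
          -0.108
        ]
      ],
      "psi": 0.025
    },
    {
      "weight": 0.5,
      "kappa": [
        2.505,
        3.315
      ],
      "phi": [
        [
          0.419,
          0.135
        ],
        [
          0.135,
          0.435
        ]
      ],
      "alpha": -0.207,
      "gamma_lin": [
        0.078,
        0.429
      ],
      "gamma_quad": [
        [
          0.023,
          -0.008
        ],
        [
          -0.008,
          -0.053
        ]
      ],
      "psi": 0.026
    }
  ]
}
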