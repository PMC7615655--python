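{
  "name": "reductive_branch",
  "metabolites": [
    {
      "name": "PYR",
      "n_carbons": 3,
      "symmetric": false
    },
    {
      "name": "OAA",
      "n_carbons": 4,
      "symmetric": false
    },
    {
      "name": "MAL",
      "n_carbons": 4,
      "symmetric": false
    },
    {
      "name": "FUM",
      "n_carbons": 4,
      "symmetric": true
    },
    {
      "name": "ASP",
      "n_carbons": 4,
      "symmetric": false
    },
    {
      "name": "SUC",
      "n_carbons": 4,
      "symmetric": true
    }
  ],
  "inputs": [
    "PYR"
  ],
  "co2_policy": {
    "recycle_fraction": 0.0
  },
  "reactions": [
    {
      "name": "PC",
      "substrates": [
        "PYR"
      ],
      "products": [
        "OAA"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "CO2_IN"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "MDHr",
      "substrates": [
        "OAA"
      ],
      "products": [
        "MAL"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "FHr",
      "substrates": [
        "MAL"
      ],
      "products": [
        "FUM"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4"
        ]
      ],
      "losses": [],
      "symmetric_products": [
        "FUM"
      ]
    },
    {
      "name": "FR",
      "substrates": [
        "FUM"
      ],
      "products": [
        "SUC"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4"
        ]
      ],
      "losses": [],
      "symmetric_products": [
        "SUC"
      ]
    },
    {
      "name": "AATr",
      "substrates": [
        "OAA"
      ],
      "products": [
        "ASP"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    }
  ]
}
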