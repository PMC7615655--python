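{
  "name": "glycolysis",
  "metabolites": [
    {
      "name": "GLC",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "G6P",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "F6P",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "DHAP",
      "n_carbons": 3,
      "symmetric": false
    },
    {
      "name": "GAP",
      "n_carbons": 3,
      "symmetric": false
    },
    {
      "name": "PYR",
      "n_carbons": 3,
      "symmetric": false
    },
    {
      "name": "G3P",
      "n_carbons": 3,
      "symmetric": false
    },
    {
      "name": "ACD",
      "n_carbons": 2,
      "symmetric": false
    }
  ],
  "inputs": [
    "GLC"
  ],
  "co2_policy": {
    "recycle_fraction": 0.0
  },
  "reactions": [
    {
      "name": "HK",
      "substrates": [
        "GLC"
      ],
      "products": [
        "G6P"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4",
          "S0.C5",
          "S0.C6"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "PGI",
      "substrates": [
        "G6P"
      ],
      "products": [
        "F6P"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4",
          "S0.C5",
          "S0.C6"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "FBA",
      "substrates": [
        "F6P"
      ],
      "products": [
        "DHAP",
        "GAP"
      ],
      "atom_map": [
        [
          "S0.C3",
          "S0.C2",
          "S0.C1"
        ],
        [
          "S0.C4",
          "S0.C5",
          "S0.C6"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "GPD",
      "substrates": [
        "DHAP"
      ],
      "products": [
        "G3P"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "TPI",
      "substrates": [
        "DHAP"
      ],
      "products": [
        "GAP"
      ],
      "atom_map": [
        [
          "S0.C3",
          "S0.C2",
          "S0.C1"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "PYK",
      "substrates": [
        "GAP"
      ],
      "products": [
        "PYR"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "PDC",
      "substrates": [
        "PYR"
      ],
      "products": [
        "ACD"
      ],
      "atom_map": [
        [
          "S0.C2",
          "S0.C3"
        ]
      ],
      "losses": [
        {
          "slot": 0,
          "carbon": 1,
          "fate": "co2"
        }
      ],
      "symmetric_products": []
    }
  ]
}
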