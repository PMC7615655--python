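{
  "name": "ppp_shunt",
  "metabolites": [
    {
      "name": "G6P",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "6PGA",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "Ru5P",
      "n_carbons": 5,
      "symmetric": false
    },
    {
      "name": "F6P",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "GAP",
      "n_carbons": 3,
      "symmetric": false
    }
  ],
  "inputs": [
    "G6P"
  ],
  "co2_policy": {
    "recycle_fraction": 0.0
  },
  "reactions": [
    {
      "name": "G6PDH",
      "substrates": [
        "G6P"
      ],
      "products": [
        "6PGA"
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
      "name": "6PGDH",
      "substrates": [
        "6PGA"
      ],
      "products": [
        "Ru5P"
      ],
      "atom_map": [
        [
          "S0.C2",
          "S0.C3",
          "S0.C4",
          "S0.C5",
          "S0.C6"
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
    },
    {
      "name": "nonox_ppp",
      "substrates": [
        "Ru5P",
        "Ru5P",
        "Ru5P"
      ],
      "products": [
        "F6P",
        "F6P",
        "GAP"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S1.C1",
          "S0.C3",
          "S0.C4",
          "S0.C5"
        ],
        [
          "S2.C1",
          "S2.C2",
          "S1.C2",
          "S1.C3",
          "S1.C4",
          "S1.C5"
        ],
        [
          "S2.C3",
          "S2.C4",
          "S2.C5"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    }
  ]
}
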