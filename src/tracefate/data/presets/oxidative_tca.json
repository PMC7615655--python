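{
  "name": "oxidative_tca",
  "metabolites": [
    {
      "name": "ACA",
      "n_carbons": 2,
      "symmetric": false
    },
    {
      "name": "OAA",
      "n_carbons": 4,
      "symmetric": false
    },
    {
      "name": "CIT",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "ICT",
      "n_carbons": 6,
      "symmetric": false
    },
    {
      "name": "AKG",
      "n_carbons": 5,
      "symmetric": false
    },
    {
      "name": "SUC",
      "n_carbons": 4,
      "symmetric": true
    },
    {
      "name": "ASP",
      "n_carbons": 4,
      "symmetric": false
    },
    {
      "name": "FUM",
      "n_carbons": 4,
      "symmetric": true
    },
    {
      "name": "MAL",
      "n_carbons": 4,
      "symmetric": false
    }
  ],
  "inputs": [
    "ACA"
  ],
  "co2_policy": {
    "recycle_fraction": 0.0
  },
  "reactions": [
    {
      "name": "CS",
      "substrates": [
        "ACA",
        "OAA"
      ],
      "products": [
        "CIT"
      ],
      "atom_map": [
        [
          "S1.C4",
          "S1.C3",
          "S1.C2",
          "S0.C2",
          "S0.C1",
          "S1.C1"
        ]
      ],
      "losses": [],
      "symmetric_products": []
    },
    {
      "name": "ACO",
      "substrates": [
        "CIT"
      ],
      "products": [
        "ICT"
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
      "name": "IDH",
      "substrates": [
        "ICT"
      ],
      "products": [
        "AKG"
      ],
      "atom_map": [
        [
          "S0.C1",
          "S0.C2",
          "S0.C3",
          "S0.C4",
          "S0.C5"
        ]
      ],
      "losses": [
        {
          "slot": 0,
          "carbon": 6,
          "fate": "co2"
        }
      ],
      "symmetric_products": []
    },
    {
      "name": "AKGDH",
      "substrates": [
        "AKG"
      ],
      "products": [
        "SUC"
      ],
      "atom_map": [
        [
          "S0.C2",
          "S0.C3",
          "S0.C4",
          "S0.C5"
        ]
      ],
      "losses": [
        {
          "slot": 0,
          "carbon": 1,
          "fate": "co2"
        }
      ],
      "symmetric_products": [
        "SUC"
      ]
    },
    {
      "name": "SDH",
      "substrates": [
        "SUC"
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
      "name": "FH",
      "substrates": [
        "FUM"
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
      "name": "MDH",
      "substrates": [
        "MAL"
      ],
      "products": [
        "OAA"
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
      "name": "AAT",
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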