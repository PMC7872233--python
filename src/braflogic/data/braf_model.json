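{
  "nodes": [
    {
      "name": "EGF",
      "is_input": true
    },
    {
      "name": "HGF",
      "is_input": true
    },
    {
      "name": "FGF",
      "is_input": true
    },
    {
      "name": "NRG1",
      "is_input": true
    },
    {
      "name": "SOX10",
      "is_input": true
    },
    {
      "name": "ATM",
      "is_input": true
    },
    {
      "name": "EGFR"
    },
    {
      "name": "ERBB2"
    },
    {
      "name": "ERBB3"
    },
    {
      "name": "MET"
    },
    {
      "name": "FGFR2"
    },
    {
      "name": "GRB2"
    },
    {
      "name": "SOS"
    },
    {
      "name": "GAB1"
    },
    {
      "name": "SPRY"
    },
    {
      "name": "RAS"
    },
    {
      "name": "BRAF"
    },
    {
      "name": "CRAF"
    },
    {
      "name": "MEK",
      "max_level": 2
    },
    {
      "name": "ERK",
      "max_level": 2
    },
    {
      "name": "PI3K"
    },
    {
      "name": "PTEN"
    },
    {
      "name": "PDPK1"
    },
    {
      "name": "AKT"
    },
    {
      "name": "mTOR"
    },
    {
      "name": "p70",
      "max_level": 2
    },
    {
      "name": "p53"
    },
    {
      "name": "p21"
    },
    {
      "name": "FOXD3"
    },
    {
      "name": "Proliferation",
      "max_level": 2
    }
  ],
  "rules": {
    "EGFR": "EGF & !ERK & !FOXD3",
    "ERBB2": "EGF | NRG1",
    "ERBB3": "NRG1 & FOXD3",
    "MET": "HGF",
    "FGFR2": "FGF",
    "GRB2": "EGFR | ERBB2 | ERBB3 | MET | FGFR2",
    "SOS": "GRB2 & !SPRY",
    "GAB1": "(EGFR | MET) & !ERK",
    "SPRY": "ERK",
    "RAS": "SOS",
    "BRAF": "RAS",
    "CRAF": "RAS",
    "MEK": [
      "BRAF | CRAF",
      "BRAF"
    ],
    "ERK": [
      "MEK",
      "MEK:2"
    ],
    "PI3K": "GAB1 | ERBB3",
    "PTEN": "p53",
    "PDPK1": "PI3K & !PTEN",
    "AKT": "PI3K & !PTEN",
    "mTOR": "AKT & !p70:2",
    "p70": [
      "PDPK1 | mTOR",
      "PDPK1 & mTOR"
    ],
    "p53": "ATM",
    "p21": "p53 & !AKT",
    "FOXD3": "SOX10 & !ERK",
    "Proliferation": [
      "!p21 & (ERK | p70:2)",
      "!p21 & ERK:2 & p70"
    ]
  },
  "phenotypes": {
    "Proliferation": "Proliferation"
  },
  "initial_profiles": {
    "generic": {},
    "IC_CRC": {
      "SOX10": 0.0,
      "EGF": 1.0,
      "NRG1": 0.0
    },
    "IC_melanoma": {
      "SOX10": 1.0,
      "EGF": 0.0,
      "NRG1": 1.0
    }
  }
}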