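{
  "version": "SSSL-NIR-V3",
  "primary_components": {
    "units": "g 100g-1 sample dry matter",
    "ranges": {
      "crude_protein": [7.558, 20.658],
      "ash": [2.449, 6.156],
      "crude_fat": [0.0, 7.702],
      "crude_fiber": [1.593, 21.133],
      "moisture": [6.41, 10.17],
      "total_amino_acids": [6.235, 17.499]
    }
  },
  "amino_acids": {
    "units": "g 100g-1 protein",
    "ranges": {
      "alanine": [0.31, 0.792],
      "arginine": [0.475, 1.849],
      "aspartic_acid": [0.586, 1.618],
      "cysteine": [0.111, 0.341],
      "glutamic_acid": [0.818, 2.961],
      "glycine": [0.42, 1.123],
      "histidine": [0.177, 0.594],
      "isoleucine": [0.299, 0.792],
      "leucine": [0.453, 1.222],
      "lysine": [0.409, 1.079],
      "methionine": [0.133, 0.374],
      "phenylalanine": [0.287, 0.781],
      "proline": [0.265, 0.704],
      "serine": [0.265, 0.726],
      "taurine": [0.128, 0.242],
      "threonine": [0.254, 0.638],
      "tryptophan": [0.067, 0.186],
      "tyrosine": [0.221, 0.539],
      "valine": [0.354, 0.902],
      "hydroxylysine": [0.0, 0.033],
      "hydroxyproline": [0.032, 0.145]
    }
  },
  "excluded_from_analysis": ["hydroxylysine", "hydroxyproline"]
}
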