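{
  "source": "WHO/FAO/UNU (2007) suggested indispensable amino acid requirements",
  "units": "mg g-1 protein",
  "basis": "14% moisture",
  "requirements": {
    "histidine": {"adult": 15, "infant": 20},
    "isoleucine": {"adult": 30, "infant": 32},
    "leucine": {"adult": 59, "infant": 66},
    "lysine": {"adult": 45, "infant": 57},
    "saa": {"adult": 22, "infant": 28},
    "aaa": {"adult": 38, "infant": 52},
    "threonine": {"adult": 23, "infant": 31},
    "tryptophan": {"adult": 6, "infant": 8.5},
    "valine": {"adult": 39, "infant": 43}
  },
  "panel_mean_profile": {
    "histidine": 27.28,
    "isoleucine": 38.83,
    "leucine": 59.36,
    "lysine": 55.39,
    "saa": 36.76,
    "aaa": 63.8,
    "threonine": 31.38,
    "tryptophan": 9.96,
    "valine": 44.39
  },
  "panel_sd_profile": {
    "histidine": 0.73,
    "isoleucine": 1.19,
    "leucine": 2.39,
    "lysine": 2.87,
    "saa": 1.47,
    "aaa": 2.0,
    "threonine": 1.48,
    "tryptophan": 0.6,
    "valine": 1.81
  },
  "crude_components": {
    "crude_protein": {"mean": 14.02, "sd": 1.69, "units": "g 100g-1"},
    "ash": {"mean": 2.69, "sd": 0.26, "units": "g 100g-1"},
    "crude_fat": {"mean": 3.62, "sd": 0.72, "units": "g 100g-1"},
    "total_amino_acids": {"mean": 828.71, "sd": 20.74, "units": "mg g-1 protein"}
  }
}
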