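{
  "generator": "scripts/make_model_data.py",
  "wavelength_nm": [
    400,
    2500,
    1
  ],
  "files": [
    "leaf_coefficients.csv",
    "soil_endmembers.csv"
  ],
  "provenance": "synthetic analytic tables; see generator docstring for the qualitative constraints they encode",
  "constraints": {
    "pigments_zero_above_nm": 900,
    "water_peaks_nm": [
      970,
      1200,
      1450,
      1940
    ],
    "protein_peaks_nm": [
      1510,
      2054,
      2172
    ],
    "cbc_features_nm": [
      1730,
      2100,
      2300
    ],
    "soil_featureless_near_nm": 2100
  }
}
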