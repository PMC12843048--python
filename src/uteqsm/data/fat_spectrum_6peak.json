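{
  "name": "uteqsm-6peak-v1",
  "description": "Six-peak triglyceride proton spectrum used as the default fat model. Shifts are in ppm relative to the water resonance (negative = lower frequency); relative amplitudes sum to 1. This is a synthetic calibration table for this package: peak positions follow the usual triglyceride assignments (methyl, bulk methylene, allylic/alpha-carboxyl, diacyl, glycerol/olefinic region) with amplitudes weighted so the amplitude-weighted mean shift is about -3.36 ppm (~ -429 Hz at 3 T), consistent with the ~-440 Hz dominant methylene shift. Replace with a scanner- or tissue-specific table via FatSpectrum for quantitative fat work.",
  "reference_note": "synthetic calibration artifact; not a measured spectrum",
  "peaks": [
    {"shift_ppm": -3.90, "amplitude": 0.12},
    {"shift_ppm": -3.50, "amplitude": 0.78},
    {"shift_ppm": -2.70, "amplitude": 0.04},
    {"shift_ppm": -2.05, "amplitude": 0.02},
    {"shift_ppm": -0.50, "amplitude": 0.03},
    {"shift_ppm": 0.55, "amplitude": 0.01}
  ]
}
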