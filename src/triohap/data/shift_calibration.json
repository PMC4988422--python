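{
  "description": "Published dye-shift calibration for the PAH STR/VNTR trio panel: per-dye mean shift (observed minus reference size, bp) at each reference allele, measured across 100 co-electrophoresed family trios, plus the intra-/inter-dye shift variability (SD, bp) observed before and after polynomial correction. Missing cells (allele never observed for that dye) are null.",
  "reference_sizes": [226, 230, 234, 238, 242, 246, 250, 254, 334, 454, 484, 514],
  "mean_shift": {
    "FAM":   [-2.26, -2.34, -2.35, -2.40, -2.52, -2.52, -2.48, -2.48, -2.46, -1.91, -2.16, -2.07],
    "HEX":   [-2.13, -2.19, -2.23, -2.27, -2.38, -2.42, -2.33, -2.37, -2.38, -1.90, -2.10, -1.92],
    "TAMRA": [-0.46, -0.52, -0.63, -0.72, -0.81, -0.81, -0.81, -0.78, -1.43, -0.98, -1.37, -1.18]
  },
  "intra_dye_sd": {
    "FAM":   [0.103, 0.108, 0.089, 0.093, 0.104, 0.101, 0.073, 0.110, 0.319, 0.322, 0.431, 0.122],
    "HEX":   [0.132, 0.097, 0.089, 0.102, 0.078, 0.089, 0.104, 0.095, 0.308, 0.349, 0.480, 0.077],
    "TAMRA": [0.070, 0.126, 0.091, 0.115, 0.115, 0.097, 0.080, null, 0.272, 0.340, 0.489, 0.125]
  },
  "inter_dye_sd_before": [0.76, 0.78, 0.72, 0.80, 0.89, 0.64, 0.77, 0.35, 0.49, 0.45, 0.44, 0.41],
  "inter_dye_sd_after":  [0.05, 0.04, 0.04, 0.04, 0.04, 0.02, 0.05, 0.02, 0.08, 0.07, 0.11, 0.03]
}
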