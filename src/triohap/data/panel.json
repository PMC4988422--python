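{
  "markers": [
    {
      "name": "STR",
      "repeat_unit_bp": 4,
      "size_range": [200, 300],
      "ladder": [226, 230, 234, 238, 242, 246, 250, 254],
      "tolerance_bp": 1.5
    },
    {
      "name": "VNTR",
      "repeat_unit_bp": 30,
      "size_range": [320, 600],
      "ladder": [334, 454, 484, 514],
      "tolerance_bp": 5.0
    }
  ],
  "dye_assignment": {"child": "FAM", "father": "HEX", "mother": "TAMRA"},
  "correction_degree": 6,
  "alpha": 0.01
}
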