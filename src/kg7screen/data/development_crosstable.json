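{
  "description": "KG-7 score distribution by comprehensive-GA status in the development cohort (N=1069 complete cases). Cases = abnormal GA (deficits in >=2 of 6 domains).",
  "levels": [0, 1, 2, 3, 4, 5, 6, 7],
  "normal_ga": [0, 0, 0, 3, 20, 102, 135, 46],
  "abnormal_ga": [121, 132, 124, 115, 145, 88, 34, 4]
}
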