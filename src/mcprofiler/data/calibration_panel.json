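{
 "description": "Synthetic calibration panel: 25 MC-profile sources, five shape families at five average-methylation levels (0.1-0.9), enriched for intermediate methylation. Each shape carries a 4% uniform error floor emulating bisulfite non-conversion and sequencing error, which keep every methylation class minimally populated in real amplicon data.",
 "sources": {
  "binomial_m10": [
   0.637856,
   0.287936,
   0.054656,
   0.011456,
   0.008096
  ],
  "binomial_m30": [
   0.238496,
   0.403136,
   0.262016,
   0.080576,
   0.015776
  ],
  "binomial_m50": [
   0.068,
   0.248,
   0.368,
   0.248,
   0.068
  ],
  "binomial_m70": [
   0.015776,
   0.080576,
   0.262016,
   0.403136,
   0.238496
  ],
  "binomial_m90": [
   0.008096,
   0.011456,
   0.054656,
   0.287936,
   0.637856
  ],
  "bimodal_m10": [
   0.872,
   0.008,
   0.008,
   0.008,
   0.104
  ],
  "bimodal_m30": [
   0.68,
   0.008,
   0.008,
   0.008,
   0.296
  ],
  "bimodal_m50": [
   0.488,
   0.008,
   0.008,
   0.008,
   0.488
  ],
  "bimodal_m70": [
   0.296,
   0.008,
   0.008,
   0.008,
   0.68
  ],
  "bimodal_m90": [
   0.104,
   0.008,
   0.008,
   0.008,
   0.872
  ],
  "blend_m10": [
   0.754928,
   0.147968,
   0.031328,
   0.009728,
   0.056048
  ],
  "blend_m30": [
   0.459248,
   0.205568,
   0.135008,
   0.044288,
   0.155888
  ],
  "blend_m50": [
   0.278,
   0.128,
   0.188,
   0.128,
   0.278
  ],
  "blend_m70": [
   0.155888,
   0.044288,
   0.135008,
   0.205568,
   0.459248
  ],
  "blend_m90": [
   0.056048,
   0.009728,
   0.031328,
   0.147968,
   0.754928
  ],
  "peaked_m10": [
   0.4999973496,
   0.3724806011,
   0.0893266149,
   0.0261464206,
   0.0120490137
  ],
  "peaked_m30": [
   0.1310596398,
   0.5595150425,
   0.2322292832,
   0.0580323159,
   0.0191637187
  ],
  "peaked_m50": [
   0.0389189548,
   0.1465691416,
   0.6290238073,
   0.1465691416,
   0.0389189548
  ],
  "peaked_m70": [
   0.0191637187,
   0.0580323159,
   0.2322292832,
   0.5595150425,
   0.1310596398
  ],
  "peaked_m90": [
   0.0120490137,
   0.0261464206,
   0.0893266149,
   0.3724806011,
   0.4999973496
  ],
  "uniform_blend_m10": [
   0.536,
   0.104,
   0.104,
   0.104,
   0.152
  ],
  "uniform_blend_m30": [
   0.44,
   0.104,
   0.104,
   0.104,
   0.248
  ],
  "uniform_blend_m50": [
   0.344,
   0.104,
   0.104,
   0.104,
   0.344
  ],
  "uniform_blend_m70": [
   0.248,
   0.104,
   0.104,
   0.104,
   0.44
  ],
  "uniform_blend_m90": [
   0.152,
   0.104,
   0.104,
   0.104,
   0.536
  ]
 }
}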