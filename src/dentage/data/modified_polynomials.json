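[
 {
  "sex": "M",
  "degree": 5,
  "coefficients": [
   3.04471040683471e-07,
   -0.000104409502065903,
   0.0141677515859983,
   -0.948508480952154,
   31.3447464323149,
   -403.48344718101
  ],
  "score_domain": [
   39.92,
   99.25
  ],
  "provenance": "Published sex-specific degree-5 least-squares fit of chronological age on the seven-tooth maturity score for an eastern Chinese reference cohort (ages 5-16, n=2367), coefficients stored digit-for-digit as printed. Score domain = span of the published lookup table for that sex."
 },
 {
  "sex": "F",
  "degree": 5,
  "coefficients": [
   4.61590755570541e-07,
   -0.000154896783268403,
   0.0203841924163241,
   -1.31156808447141,
   41.2383716718296,
   -501.400716931816
  ],
  "score_domain": [
   41.82,
   100.1
  ],
  "provenance": "Published sex-specific degree-5 least-squares fit of chronological age on the seven-tooth maturity score for an eastern Chinese reference cohort (ages 5-16, n=2367), coefficients stored digit-for-digit as printed. Score domain = span of the published lookup table for that sex."
 }
]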