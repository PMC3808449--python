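{
 "default_rule": true,
 "format": "immunopep-model",
 "importance": [0.0, 0.0, 0.1, 0.31, 0.3, 0.29, 0.26, 0.18, 0.0],
 "log_enrichment": {
  "A": 0.127,
  "C": -0.175,
  "D": 0.072,
  "E": 0.325,
  "F": 0.38,
  "G": 0.11,
  "H": 0.105,
  "I": 0.432,
  "K": -0.7,
  "L": -0.036,
  "M": -0.57,
  "N": -0.021,
  "P": -0.036,
  "Q": -0.376,
  "R": 0.168,
  "S": -0.537,
  "T": 0.126,
  "V": 0.134,
  "W": 0.719,
  "Y": -0.012
 },
 "masks": {
  "HLA-B*08:01": [2, 5, 9]
 },
 "metadata": {
  "name": "reference MHC-I 9mer immunogenicity model",
  "provenance": "log-enrichment scores and position-importance weights transcribed by the package authors from the published reference predictor distributed through the IEDB analysis resource; anchor-mask table limited to the default {P1,P2,P9} rule plus HLA-B*08:01 (P2/P5/P9)"
 },
 "version": 1
}
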