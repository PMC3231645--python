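{
  "printed_B": [[0.23, 0.57, 0.2],
                [0.23, 0.53, 0.21],
                [0.26, 0.54, 0.2]],
  "recomputed_B": [[0.23, 0.57, 0.20],
                   [0.23, 0.56, 0.21],
                   [0.24, 0.56, 0.20]],
  "printed_V": [0.2345, 0.5575, 0.202],
  "recomputed_V": [0.2345, 0.5635, 0.202],
  "printed_V_normalized": [0.2359, 0.5609, 0.2032],
  "decision": "B4L",
  "printed_discrepancy": [
    "B[1][1] printed 0.53; weighted-average composition of the membership table gives 0.56",
    "B[2][0] printed 0.26; recomputation gives 0.24",
    "B[2][1] printed 0.54; recomputation gives 0.56",
    "V[1] printed 0.5575; recomputation from the recomputed B gives 0.5635",
    "V[0] and V[2] as printed agree with recomputation, which is consistent with typos in B[1][1], B[2][0], B[2][1] and V[1] rather than a different composition rule"
  ]
}
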