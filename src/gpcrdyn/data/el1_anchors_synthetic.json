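{
  "comment": "Reconstructed (synthetic) EL1 alignment window for D2R/D3R; the conserved Trp anchors EL1.50. Residue identities away from the anchor are placeholders.",
  "anchor_columns": {"EL1.50": 6},
  "segment_windows": {"EL1": [4, 9]},
  "starts": {"D2R": 95, "D3R": 92}
}
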