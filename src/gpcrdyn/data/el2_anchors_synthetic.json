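{
  "comment": "Reconstructed (synthetic) EL2 alignment window for D2R/D3R; the disulfide Cys anchors EL2.50. Residue identities away from the anchor are placeholders.",
  "anchor_columns": {"EL2.50": 9},
  "segment_windows": {"EL2": [5, 13]},
  "starts": {"D2R": 174, "D3R": 174}
}
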