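>D2R reconstructed EL2 window (synthetic stand-in alignment; anchor Cys182)
LNNADQNECIIAN
>D3R reconstructed EL2 window (synthetic stand-in alignment; anchor Cys181)
L-NADQNECSVAN
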