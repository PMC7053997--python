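>D2R reconstructed EL1 window (synthetic stand-in alignment; anchor Trp100)
AVSEKWVVYLE
>D3R reconstructed EL1 window (synthetic stand-in alignment; anchor Trp96)
-AGSEWVQYLE
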