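# atom map for CYSP: source target
# ccd-order: C5X C1X O3X C2X N4X
C1X C1
C2X C2
O3X O3
N4X N4
C5X C5
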