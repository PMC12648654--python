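# atom map for POPC: source target
# ccd-order: O8X C2X P6X C1X N4X C5X O3X C7X C10X C9X
C1X C1
C2X C2
O3X O3
N4X N4
C5X C5
P6X P6
C7X C7
O8X O8
C9X C9
C10X C10
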