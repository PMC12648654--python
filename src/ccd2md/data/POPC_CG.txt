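# bead map for POPC: bead atoms...
B1 C1 C2
B2 O3 N4
B3 C5 P6
B4 C7 O8
B5 C9 C10
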