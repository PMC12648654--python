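# bead map for POPS: bead atoms...
B1 C1 C2
B2 O3 N4
B3 C5 P6
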