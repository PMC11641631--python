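H EISD840101
D Consensus normalized hydrophobicity scale (hand-reconstructed synthetic
D stand-in for the real AAindex record; only the proline value -0.07 is
D cross-checked against an independent source)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.25   -1.76   -0.64   -0.72    0.04   -0.69   -0.62    0.16   -0.40    0.73
    0.53   -1.10    0.26    0.61   -0.07   -0.26   -0.18    0.37    0.02    0.54
//
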