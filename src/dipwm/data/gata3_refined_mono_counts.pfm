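>GATA3 refined mono-nucleotide counts (68 promoter-extracted sites)
A [ 27  0 66  0 43 16 ]
C [ 15  1  0  0  1  3 ]
G [  4 67  1  5  4 41 ]
T [ 22  0  1 63 20  8 ]
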