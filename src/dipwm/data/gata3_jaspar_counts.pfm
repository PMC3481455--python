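>GATA3 JASPAR aligned-site counts (63 sites)
A [ 25  0 61  0 39 15 ]
C [ 14  1  0  0  1  3 ]
G [  4 62  1  5  4 37 ]
T [ 20  0  1 58 19  8 ]
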