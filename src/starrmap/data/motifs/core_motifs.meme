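MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.250000 C 0.250000 G 0.250000 T 0.250000

MOTIF YY1_syn
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.100000 0.700000 0.100000 0.100000
0.700000 0.100000 0.100000 0.100000
0.700000 0.100000 0.100000 0.100000
0.100000 0.100000 0.700000 0.100000
0.940000 0.020000 0.020000 0.020000
0.020000 0.020000 0.020000 0.940000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000
0.100000 0.700000 0.100000 0.100000
0.100000 0.100000 0.700000 0.100000
0.100000 0.100000 0.700000 0.100000
0.100000 0.700000 0.100000 0.100000

MOTIF ETS_syn
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.700000 0.100000 0.100000 0.100000
0.100000 0.700000 0.100000 0.100000
0.100000 0.700000 0.100000 0.100000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000
0.940000 0.020000 0.020000 0.020000
0.940000 0.020000 0.020000 0.020000
0.100000 0.100000 0.700000 0.100000
0.100000 0.100000 0.100000 0.700000
0.100000 0.100000 0.700000 0.100000
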