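symbol	monoisotopic_mass
C	12.0
H	1.007825032
N	14.003074005
O	15.994914620
S	31.972071174
P	30.973761998
Na	22.989769282
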