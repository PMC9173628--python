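residue	pka
ASP	3.9
GLU	4.2
HIS	6.5
LYS	10.5
ARG	12.5
CYS	8.3
TYR	10.1
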