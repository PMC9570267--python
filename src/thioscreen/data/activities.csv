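compound,cell_line,ic50_uM
2H,W138,
2H,A549,
2H,MCF-7,
2H,HeLa,
2H,HCT,22.80
2H,HepG2,
6H,W138,
6H,A549,
6H,MCF-7,
6H,HeLa,
6H,HCT,43.25
6H,HepG2,
7H,W138,140.48
7H,A549,35.09
7H,MCF-7,24.08
7H,HeLa,30.42
7H,HCT,1.95
7H,HepG2,9.98
9H,W138,0.34
9H,A549,0.28
9H,MCF-7,0.32
9H,HeLa,0.19
9H,HCT,0.06
9H,HepG2,1.112
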