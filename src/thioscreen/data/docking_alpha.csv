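compound,target,dg_kcalmol,ki_nM,n_hbonds
2H,topo2a,-9.29,155.7,5
6H,topo2a,-9.17,189.18,5
7H,topo2a,-9.23,170.11,5
9H,topo2a,-8.53,555.3,2
Etoposide,topo2a,-8.39,708.84,5
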