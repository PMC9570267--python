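compound,target,dg_kcalmol,ki_nM,n_hbonds
2H,topo2b,-9.29,154.3,4
6H,topo2b,-10.07,41.62,4
7H,topo2b,-9.34,142.45,2
9H,topo2b,-9.16,193.43,3
Etoposide,topo2b,-11.59,3.17,4
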