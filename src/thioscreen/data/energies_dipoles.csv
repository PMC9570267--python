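compound,phase,e_total_au,dipole_D
2H,gas,-1483.19061,6.96
2H,aqueous,-1483.22089,11.02
6H,gas,-1687.75484,10.68
6H,aqueous,-1687.79006,15.26
7H,gas,-1597.74680,7.78
7H,aqueous,-1597.77917,12.19
9H,gas,-1617.19402,6.59
9H,aqueous,-1617.22616,10.44
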