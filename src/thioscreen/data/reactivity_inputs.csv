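compound,phase,e_homo_au,e_lumo_au,suspect
2H,gas,-0.23738,-0.11034,false
2H,aqueous,-0.23132,-0.10799,false
6H,gas,-0.24851,-0.12131,false
6H,aqueous,-0.23470,-0.11624,false
7H,gas,-0.22399,-0.10882,false
7H,aqueous,-0.22796,-0.10734,false
9H,aqueous,-0.22796,-0.10734,true
9H,aqueous,-0.20005,-0.10646,false
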