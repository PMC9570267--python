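compound,pol_A3,mr_A3,vol_A3,sag_A2,he_kcalmol
2H,40.88,101.87,739.85,554.14,-11.73
6H,42.72,108.18,998.3,586.26,-16.69
7H,43.35,108.33,1014.72,598.73,-13.42
9H,45.9,116.3,1070.91,621.57,-10.22
Etoposide,55.15,138.73,1448.08,808.26,-25.39
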