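compound,logp,mw_da,hbd,hba,n_rotb,psa_A2,logd74
2H,1.39,359.4,3,4,1,70.23,2.310
6H,-2.52,404.4,3,6,2,113.37,2.250
7H,1.14,389.43,3,5,2,79.46,2.152
9H,1.66,402.47,3,5,2,73.47,2.416
Etoposide,1.27,588.56,3,13,5,160.83,1.15
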