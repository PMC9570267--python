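parameter,experimental,"HF/6-311++G(d,p)","MP2/6-311++G(d,p)","B3LYP/6-311++G(d,p)",HF/cc-pVDZ,MP2/cc-pVDZ,B3LYP/cc-pVDZ
"R(N1,C2)",1.351,1.353,1.380,1.378,1.355,1.382,1.380
"R(N1,C6)",1.371,1.374,1.376,1.374,1.374,1.377,1.375
"R(N1,H7)",1.030,0.994,1.011,1.010,0.998,1.016,1.014
"R(C2,N3)",1.357,1.350,1.376,1.370,1.351,1.376,1.370
"R(C2,S8)",1.683,1.661,1.643,1.662,1.665,1.658,1.668
"R(N3,C4)",1.394,1.398,1.414,1.417,1.398,1.418,1.419
"R(N3,H9)",1.030,0.998,1.015,1.013,1.002,1.021,1.018
"R(C4,C5)",1.442,1.460,1.458,1.456,1.462,1.463,1.460
"R(C4,O10)",1.235,1.187,1.220,1.214,1.190,1.222,1.217
"R(C5,C6)",1.354,1.328,1.356,1.348,1.332,1.362,1.353
"R(C5,H11)",1.080,1.070,1.082,1.079,1.077,1.090,1.088
"R(C6,H12)",1.080,1.073,1.085,1.083,1.080,1.093,1.091
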