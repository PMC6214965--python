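group,uiv,liv,n_patients
G1,T2,T12,8
G2,T3,T12,10
G3,T4,T12,14
G4,T2,L1,12
G5,T3,L1,8
G6,T4,L1,12
G7,T3,T11,2
G8,T2,T10,1
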