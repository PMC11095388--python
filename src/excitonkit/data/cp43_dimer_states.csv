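pair,state,energy_ev
C2-C10,S1,1.843
C2-C10,S2,1.943
C2-C10,S3,2.001
C7-C9,S1,1.868
C7-C9,S2,1.891
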