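name,nominal_mean_copies,wt_copies,n_replicates
A,5120,14000,3
B,640,14000,3
C,80,14000,3
D,10,14000,3
E,5,14000,20
F,2.5,14000,20
G,1.25,14000,20
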