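target,fn,n_positive,fp,n_negative,lod_printed
EGFR_DEL19,0,120,1,112,0.01%
EGFR_L858R,0,138,1,112,0.02%
EGFR_T790M,0,138,0,112,0.01%
BRAF_V600,1,135,0,112,0.01%
KRAS_EX2,0,136,0,112,0.02%
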