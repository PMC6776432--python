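target,tested,detected
EGFR_DEL19,20,0
EGFR_L858R,20,0
EGFR_T790M,20,0
BRAF_V600,20,0
KRAS_EX2,20,0
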