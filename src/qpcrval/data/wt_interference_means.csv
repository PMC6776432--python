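target,standard,mean_ct_no_wt,mean_ct_with_wt,printed_delta
BRAF_V600,A,26.97,26.97,0
BRAF_V600,B,29.61,29.99,-0.38
BRAF_V600,C,33.09,32.91,0.18
BRAF_V600,D,36.60,35.94,0.66
BRAF_V600,F,38.19,38.06,0.14
EGFR_DEL19,A,25.29,25.21,0.07
EGFR_DEL19,B,28.82,28.15,0.67
EGFR_DEL19,C,32.23,31.43,0.79
EGFR_DEL19,D,35.34,34.68,0.65
EGFR_DEL19,F,36.85,36.23,0.62
EGFR_L858R,A,26.15,26.26,-0.11
EGFR_L858R,B,29.76,29.90,-0.14
EGFR_L858R,C,33.72,33.44,0.29
EGFR_L858R,D,37.50,36.91,0.59
EGFR_L858R,F,39.39,38.95,0.44
EGFR_T790M,A,26.90,26.95,-0.06
EGFR_T790M,B,29.94,29.97,-0.02
EGFR_T790M,C,33.56,32.96,0.60
EGFR_T790M,D,36.67,36.65,0.01
EGFR_T790M,G,38.69,39.05,-0.36
KRAS_EX2,A,29.08,29.17,-0.09
KRAS_EX2,B,31.59,31.86,-0.26
KRAS_EX2,C,34.92,34.32,0.60
KRAS_EX2,D,38.04,36.10,1.94
KRAS_EX2,F,39.26,38.14,1.12
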