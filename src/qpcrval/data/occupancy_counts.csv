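target,standard,ddpcr_copies,ddpcr_is_calculated,mle_copies_printed,n_empty,n_wells,printed_percent_empty,printed_poisson_copies
BRAF_V600,A,4510,false,,,,,
BRAF_V600,B,515,false,,,,,
BRAF_V600,C,64,false,68.55,0,18,0.0%,>10
BRAF_V600,D,7,false,7.37,0,18,0.0%,>10
BRAF_V600,E,3.5,true,2.93,5,36,13.9%,1.97
BRAF_V600,F,1.75,true,2.57,18,60,30.0%,1.2
BRAF_V600,G,0.875,true,1.59,26,60,43.3%,0.84
EGFR_DEL19,A,5337,false,,,,,
EGFR_DEL19,B,571,false,,,,,
EGFR_DEL19,C,78,false,62.3,0,18,0.0%,>10
EGFR_DEL19,D,6,true,8,0,18,0.0%,>10
EGFR_DEL19,E,3,true,4.64,0,36,0.0%,>10
EGFR_DEL19,F,1.5,true,3.5,10,60,16.7%,1.79
EGFR_DEL19,G,0.75,true,2.37,25,60,41.7%,0.88
EGFR_L858R,A,5125,false,,,,,
EGFR_L858R,B,609,false,,,,,
EGFR_L858R,C,77,false,80.7,0,18,0.0%,>10
EGFR_L858R,D,11,false,11.72,0,18,0.0%,>10
EGFR_L858R,E,5.5,true,6.47,2,36,5.6%,2.89
EGFR_L858R,F,2.75,true,4.71,10,60,16.7%,1.79
EGFR_L858R,G,1.375,true,3.17,21,60,35.0%,1.05
EGFR_T790M,A,5164,false,,,,,
EGFR_T790M,B,609,false,,,,,
EGFR_T790M,C,91,false,74.93,0,18,0.0%,>10
EGFR_T790M,D,9,false,11.03,0,18,0.0%,>10
EGFR_T790M,E,4.5,true,5.81,3,36,8.3%,2.48
EGFR_T790M,F,2.25,true,3.69,7,60,11.7%,2.15
EGFR_T790M,G,1.125,true,3.03,27,60,45.0%,0.8
EGFR_WT,A,13980,false,,,,,
EGFR_WT,B,1536,false,,,,,
EGFR_WT,C,200,false,130.35,0,18,0.0%,>10
EGFR_WT,D,19,false,26.53,0,18,0.0%,>10
EGFR_WT,E,9.5,true,13.5,0,24,0.0%,>10
EGFR_WT,F,4.75,true,7.91,5,40,12.5%,2.08
EGFR_WT,G,2.375,true,4.15,14,40,35.0%,1.05
KRAS_EX2,A,5048,false,,,,,
KRAS_EX2,B,585,false,,,,,
KRAS_EX2,C,82,false,70.3,0,18,0.0%,>10
KRAS_EX2,D,10,false,12.21,0,18,0.0%,>10
KRAS_EX2,E,5,true,6.93,5,36,13.9%,1.97
KRAS_EX2,F,2.5,true,4.57,18,60,30.0%,1.2
KRAS_EX2,G,1.75,true,4.37,26,60,43.3%,0.84
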