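cohort,source,target,n,positive,printed_percent
Mexico,liquid,T790M,316,64,20.25%
Mexico,liquid,L858R,316,34,10.76%
Mexico,liquid,DEL19,316,92,29.11%
Mexico,liquid,DEL19_L858R,316,126,39.87%
Mexico,tissue,DEL19_L858R,1417,472,36.70%
Columbia,liquid,T790M,128,15,11.72%
Columbia,liquid,L858R,128,12,9.38%
Columbia,liquid,DEL19,128,22,17.19%
Columbia,liquid,DEL19_L858R,128,34,26.56%
Columbia,tissue,DEL19_L858R,1939,456,25.20%
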