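target,tested,detected,printed_percent
T790M,2261,267,11.81%
L858R,2261,172,7.61%
DEL19,2261,311,13.75%
BRAF,1417,24,1.69%
KRAS,491,99,20.16%
DEL19_L858R,2261,462,20.43%
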