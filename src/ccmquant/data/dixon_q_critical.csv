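# Two-tailed critical values for Dixon's r10 ("Q") ratio, n = 3..10.
# Source: standard two-tailed tabulation (Rorabacher, Anal. Chem. 63 (1991) 139-146).
# version: 1.0
n,alpha_0.10,alpha_0.05,alpha_0.01
3,0.941,0.970,0.994
4,0.765,0.829,0.926
5,0.642,0.710,0.821
6,0.560,0.625,0.740
7,0.507,0.568,0.680
8,0.468,0.526,0.634
9,0.437,0.493,0.598
10,0.412,0.466,0.568
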