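item_id,round,variant,median,p_low,p_high,bin_low,bin_mid,bin_high,label,di,modified,converged
1,1,original,3,2,3,18,5,1,A/IA,0.275,0,0
2,1,original,2,2,3,18,6,0,A/IA,0.220,1,0
3,1,original,5,4,7,7,10,7,Neutral,0.658,1,0
4,1,original,2,1,2,23,1,0,A/IA,0.220,0,0
5,1,original,3,2,4,16,7,1,A/IA,0.299,0,0
6,1,original,4,3,6,10,10,4,Neutral,0.526,1,0
7,1,original,4,3,6,9,11,4,Neutral,0.502,1,0
8,1,original,4,3,5,11,10,3,Neutral,0.458,0,0
9,1,original,5,4,6,7,13,4,Neutral,0.539,1,0
10,1,original,4,2,5,12,10,2,A/IA,0.461,1,0
11,1,original,5,3,5,11,10,3,Neutral,0.564,1,0
12,1,original,5,5,6,5,13,6,Neutral,0.549,1,0
13,1,original,2,2,3,19,4,1,A/IA,0.229,1,0
14,1,original,2,2,3,18,5,1,A/IA,0.220,0,0
15,1,original,1,2,4,13,8,3,A/IA,0.120,0,0
16,1,original,2,2,2,23,0,1,A/IA,0.211,1,0
17,1,original,2,2,2,21,3,0,A/IA,0.203,1,0
18,1,original,2,2,5,13,10,1,A/IA,0.251,0,0
19,1,original,2,2,4,16,8,0,A/IA,0.240,1,0
20,1,original,2,2,4,17,6,1,A/IA,0.229,0,0
1,2,original,2,2,3,19,0,0,A/IA,0.220,0,0
2,2,original,3,2,3,17,2,0,A/IA,0.330,0,0
3,2,original,5,4,6,4,12,3,Neutral,0.599,0,0
4,2,original,2,1,2,19,0,0,A/IA,0.220,0,0
5,2,original,2,2,3,15,4,0,A/IA,0.220,0,0
6,2,original,4,3,4,9,9,1,Neutral,0.440,0,0
7,2,original,3,3,5,10,8,1,A/IA,0.359,0,1
8,2,original,3,2,4,10,7,2,A/IA,0.359,0,1
9,2,original,4,3,5,6,11,2,Neutral,0.479,0,0
10,2,original,3,2,3,14,4,1,A/IA,0.330,0,0
11,2,original,4,3,4,9,10,0,Neutral,0.440,0,0
12,2,original,5,3,5,6,13,0,Neutral,0.599,0,0
13,2,original,2,2,2,18,1,0,A/IA,0.203,0,0
14,2,original,2,2,2,17,2,0,A/IA,0.203,0,0
15,2,original,2,2,2,17,2,0,A/IA,0.203,0,0
16,2,original,2,2,2,19,0,0,A/IA,0.203,0,0
17,2,original,2,2,2,19,0,0,A/IA,0.203,0,0
18,2,original,3,2,3,17,2,0,A/IA,0.330,0,0
19,2,original,2,2,2,18,1,0,A/IA,0.203,0,0
20,2,original,2,2,3,15,4,0,A/IA,0.220,0,0
2m,2,modified,2,2,2,18,0,1,A/IA,0.203,1,0
3m,2,modified,4,2,4,9,8,2,Neutral,0.479,1,0
6m,2,modified,3,2,3,14,5,0,A/IA,0.330,1,1
7m,2,modified,2,2,3,15,4,0,A/IA,0.220,1,0
9a,2,modified,3,2,3,14,4,1,A/IA,0.330,1,1
9b,2,modified,2,2,4,13,3,3,A/IA,0.240,1,1
10m,2,modified,2,2,3,17,1,1,A/IA,0.220,1,0
11m,2,modified,3,2,4,12,7,0,A/IA,0.359,1,1
12m,2,modified,5,5,5,5,14,0,Neutral,0.508,1,0
13m,2,modified,2,2,3,14,5,0,A/IA,0.220,1,0
16m,2,modified,2,2,2,19,0,0,A/IA,0.203,1,0
17m,2,modified,2,2,2,19,0,0,A/IA,0.203,1,0
19m,2,modified,2,2,3,17,2,0,A/IA,0.220,1,0
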