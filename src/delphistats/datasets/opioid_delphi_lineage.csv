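child_id,parent_id,relation
2m,2,modified
3m,3,modified
6m,6,modified
7m,7,modified
9a,9,split
9b,9,split
10m,10,modified
11m,11,modified
12m,12,modified
13m,13,modified
16m,16,modified
17m,17,modified
19m,19,modified
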