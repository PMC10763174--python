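item_id,category_id,category_label
1,opioid_disease,Opioid-disease interaction
2,population,Inappropriate for the population
3,opioid_disease,Opioid-disease interaction
4,opioid_disease,Opioid-disease interaction
5,opioid_disease,Opioid-disease interaction
6,opioid_disease,Opioid-disease interaction
7,opioid_drug,Opioid-drug interaction
8,opioid_disease,Opioid-disease interaction
9,opioid_drug,Opioid-drug interaction
10,opioid_drug,Opioid-drug interaction
11,opioid_drug,Opioid-drug interaction
12,opioid_disease,Opioid-disease interaction
13,omission,Omission
14,omission,Omission
15,population,Inappropriate for the population
16,dose,Inappropriate dose
17,duration,Inappropriate duration
18,population,Inappropriate for the population
19,population,Inappropriate for the population
20,opioid_disease,Opioid-disease interaction
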