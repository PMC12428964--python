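sample_id,risk,stage_4s,therapy,mycn,profile,anchor_group
1,LR,1,none,NA,A,normal
2,LR,1,none,NA,A,normal
3,LR,0,none,NA,A,normal
4,LR,0,none,NA,A,normal
5,LR,0,none,NA,A,normal
6,LR,0,none,NA,A,normal
7,LR,0,none,NA,A,normal
8,LR,0,none,NA,A,normal
9,HR,0,none,A,B,normal
10,HR,0,none,A,C,long
11,HR,0,none,NA,B,long
12,HR,0,none,A,B,short
13,HR,0,chemotherapy,NA,C,long
14,HR,0,chemotherapy,NA,D,normal
15,HR,0,anti-GD2,NA,A,short
16,HR,0,anti-GD2,A,D,normal
17,HR,0,anti-GD2,NA,B,long
18,HR,0,anti-GD2,NA,E,nd
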