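path,po,ep,fusion_groups,y2_1,y2_2,y2_3
1,1,1,2;6,4,1,0
2,1,1,3;5,0,1,6
3,1,2,1,0,1,0
4,1,2,3;4,1,1,4
5,1,2,2,0,1,1
6,1,2,4;6,3,1,0
7,2,1,1;2,5,1,1
8,2,1,5;6,1,5,0
9,2,1,4,0,0,1
10,2,1,3,1,0,0
11,2,2,2,4,0,0
12,2,2,5,0,0,1
13,2,2,4,0,1,0
14,3,1,3,0,5,1
15,3,1,1,1,0,0
16,3,1,4,0,0,5
17,3,1,6,5,1,0
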