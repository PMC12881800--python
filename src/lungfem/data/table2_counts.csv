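case_id,artery_video,artery_ai,vein_video,vein_ai,bronchus_video,bronchus_ai
1,4,4,3,3,1,1
2,4,4,3,3,x,x
3,2,2,4,4,3,3
4,2,2,3,3,1,1
5,3,3,4,4,x,x
6,5,5,1,1,2,2
7,4,4,2,2,2,2
8,4,4,5,5,1,1
9,6,6,3,3,1,1
10,4,4,3,3,3,3
11,x,x,1,2,x,x
12,6,6,3,3,1,1
13,1,1,4,4,2,2
14,3,3,3,3,3,3
15,4,5,4,4,3,3
16,3,3,3,3,1,1
17,4,4,2,2,1,1
18,4,4,6,7,1,1
19,3,3,2,2,2,2
20,5,5,2,2,1,1
21,3,3,3,3,2,2
22,5,5,3,3,2,2
23,6,5,3,3,1,1
24,2,2,x,x,2,2
25,3,3,x,x,2,2
26,3,3,2,2,1,1
27,5,5,x,x,3,3
28,3,3,4,4,2,2
29,4,4,3,3,3,3
30,3,3,3,3,3,3
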