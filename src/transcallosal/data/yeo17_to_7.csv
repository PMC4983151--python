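network17,network7,weight
1,1,1.0
2,1,1.0
3,2,1.0
4,2,1.0
5,3,1.0
6,3,1.0
7,4,1.0
8,4,1.0
9,5,1.0
10,5,1.0
11,6,0.5
11,7,0.5
12,6,1.0
13,7,1.0
14,7,1.0
15,7,1.0
16,7,1.0
17,7,1.0
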