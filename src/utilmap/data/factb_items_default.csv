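item,domain,polarity
1,PWB,negative
2,PWB,negative
3,PWB,negative
4,PWB,negative
5,PWB,negative
6,PWB,negative
7,PWB,negative
8,SWB,positive
9,SWB,positive
10,SWB,positive
11,SWB,positive
12,SWB,positive
13,SWB,positive
14,SWB,positive
15,EWB,negative
16,EWB,positive
17,EWB,negative
18,EWB,negative
19,EWB,negative
20,EWB,negative
21,FWB,positive
22,FWB,positive
23,FWB,positive
24,FWB,positive
25,FWB,positive
26,FWB,positive
27,FWB,positive
28,BCS,negative
29,BCS,negative
30,BCS,negative
31,BCS,positive
32,BCS,negative
33,BCS,negative
34,BCS,negative
35,BCS,negative
36,BCS,positive
37,BCS,negative
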