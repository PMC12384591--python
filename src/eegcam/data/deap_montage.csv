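index,name
0,Fp1
1,AF3
2,F3
3,F7
4,FC5
5,FC1
6,C3
7,T7
8,CP5
9,CP1
10,P3
11,P7
12,PO3
13,O1
14,Oz
15,Pz
16,Fp2
17,AF4
18,Fz
19,F4
20,F8
21,FC6
22,FC2
23,Cz
24,C4
25,T8
26,CP6
27,CP2
28,P4
29,P8
30,PO4
31,O2
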