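subject,clinical,ME,MC,SE,SC,AE,AC
1,1,1,1,1,1,1,1
2,1,1,1,1,1,1,1
3,1,1,1,1,1,1,1
4,1,1,1,1,1,1,3
5,1,1,1,1,1,1,1
6,1,1,1,1,1,1,1
7,1,1,1,1,1,3,1
8,1,1,1,1,1,3,1
9,2,2,1,3,2,1,3
10,2,2,2,3,2,2,3
11,2,2,1,2,2,2,2
12,3,3,3,1,3,3,3
13,2,2,1,2,1,1,3
14,2,2,1,2,2,2,2
15,2,2,2,2,1,2,2
16,3,3,3,1,3,2,2
17,2,2,1,3,2,3,1
18,2,2,1,2,2,3,3
19,3,3,3,1,3,1,3
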