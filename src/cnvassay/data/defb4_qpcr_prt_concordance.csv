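cn,1,2,3,4,5,6,7,8
1,1,0,0,0,0,0,0,0
2,0,9,5,0,0,0,0,0
3,0,0,50,33,4,0,0,0
4,0,0,8,103,22,2,0,0
5,0,0,2,24,45,10,2,1
6,0,0,0,4,11,15,3,2
7,0,0,0,1,1,2,4,0
8,0,0,0,0,0,1,1,0
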