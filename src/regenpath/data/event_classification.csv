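code,category
0000,NO_CHANGE
0001,SV
0010,SV
0011,NO_CHANGE
0100,COMPLEX
0101,SV
0110,SV
0111,DMV
1000,COMPLEX
1001,SV
1010,SV
1011,DNMV
1100,NO_CHANGE
1101,SV
1110,SV
1111,NO_CHANGE
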