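>SYNTH_MIXED_W4
10	2	3	5
1	15	3	1
7	7	3	3
0	0	18	2
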