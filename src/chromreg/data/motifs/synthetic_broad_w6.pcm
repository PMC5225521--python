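>SYNTH_BROAD_W6
8	6	4	2
2	8	6	4
4	2	8	6
6	4	2	8
5	5	5	5
9	1	9	1
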