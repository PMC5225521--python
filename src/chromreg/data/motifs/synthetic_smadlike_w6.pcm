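>SYNTH_SMADLIKE_W6
3	4	40	3
2	3	42	3
2	40	4	4
2	4	40	4
3	42	2	3
4	40	3	3
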