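1	2
2	3
3	4
5	6
7
8
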