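# augmented network
1	2
2	3
3	4
5	6
1	9
9	4
7	10
10	8
1	11
11	3
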