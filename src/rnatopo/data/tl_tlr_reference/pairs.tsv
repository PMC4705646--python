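i	j	class
1	16	canonical
2	15	canonical
3	14	canonical
4	13	canonical
5	12	canonical
6	11	canonical
26	50	canonical
27	49	canonical
30	45	noncanonical_internal
33	44	noncanonical_internal
34	43	canonical
35	42	canonical
36	41	canonical
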