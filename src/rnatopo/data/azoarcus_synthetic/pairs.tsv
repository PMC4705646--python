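i	j	class
1	7	canonical
2	6	canonical
9	20	canonical
10	19	canonical
11	18	canonical
12	17	canonical
24	118	canonical
25	117	canonical
26	116	canonical
27	115	canonical
30	74	canonical
31	73	canonical
32	72	canonical
33	71	canonical
34	70	canonical
35	69	canonical
38	66	canonical
39	65	canonical
42	61	noncanonical_internal
45	60	noncanonical_internal
46	59	canonical
47	58	canonical
48	57	canonical
49	56	canonical
50	55	canonical
75	103	canonical
76	102	canonical
77	101	canonical
78	100	canonical
79	99	canonical
80	98	noncanonical_internal
82	95	canonical
83	94	canonical
84	93	canonical
85	92	canonical
86	91	canonical
107	156	canonical
108	155	canonical
109	154	canonical
110	153	canonical
111	152	canonical
122	148	canonical
123	147	canonical
126	143	noncanonical_internal
129	142	noncanonical_internal
130	141	canonical
131	140	canonical
132	139	canonical
133	138	canonical
159	185	canonical
160	184	canonical
161	183	canonical
163	181	canonical
164	180	canonical
165	179	canonical
166	175	canonical
167	174	canonical
168	173	canonical
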