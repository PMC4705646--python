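position	crystal
1	G12
2	G13
3	G14
4	C15
5	A16
6	C17
7	C18
8	A19
9	G20
10	G21
11	C22
12	G23
13	G24
14	A25
15	A26
16	A27
17	C28
18	G29
19	C30
20	C31
21	A32
22	U33
23	A34
24	G35
25	C36
26	C37
27	G38
28	A39
29	A40
30	G41
31	C42
32	C43
33	G44
34	A45
35	C46
36	A47
37	A48
38	G49
39	G50
40	C51
41	C52
42	U53
43	A54
44	A55
45	G56
46	G57
47	C58
48	A59
49	C60
50	G61
51	C62
52	U63
53	U64
54	G65
55	C66
56	G67
57	U68
58	G69
59	C70
60	U71
61	A72
62	U73
63	G74
64	G75
65	C76
66	C77
67	A78
68	U79
69	G80
70	U81
71	C82
72	G83
73	G84
74	C85
75	C86
76	C87
77	G88
78	A89
79	G90
80	A91
81	A92
82	G93
83	C94
84	G95
85	C96
86	G97
87	U98
88	U99
89	C100
90	G101
91	C102
92	G103
93	C104
94	G105
95	C106
96	A107
97	A108
98	G109
99	C110
100	U111
101	C112
102	G113
103	G114
104	A115
105	G116
106	U117
107	G118
108	C119
109	G120
110	G121
111	C122
112	A123
113	A124
114	A125
115	C126
116	G127
117	G128
118	C129
119	A130
120	U131
121	A132
122	G133
123	G134
124	C135
125	C136
126	U137
127	A138
128	A139
129	G140
130	G141
131	C142
132	G143
133	C144
134	A145
135	A146
136	U147
137	A148
138	G149
139	C150
140	G151
141	C152
142	U153
143	A154
144	U155
145	G156
146	G157
147	C158
148	C159
149	A160
150	A161
151	U162
152	G163
153	C164
154	C165
155	G166
156	C167
157	A168
158	A169
159	G170
160	G171
161	C172
162	A173
163	G174
164	C175
165	G176
166	G177
167	G178
168	C179
169	G180
170	A181
171	A182
172	A183
173	G184
174	C185
175	C186
176	A187
177	U188
178	A189
179	C190
180	G191
181	C192
182	A193
183	G194
184	C195
185	C196
186	A197
187	A198
188	U199
189	A200
190	A201
191	G202
192	A203
193	U204
194	A205
195	G206
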