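name	positions
5'-loop	3-5
J1/2	8
L2	13-16
J2/3	21-23
J3/4	28-29
J4/5	36-37
J5	40-45,60-64
L5	51-54
J5/4	67-68
J6	80-81,96-98
L6	87-90
J6/7	104-106
J7/3	112-114
J3/8	119-121
J8	124-129,142-146
L8	134-137
J8/7	149-151
J7/9	157-158
L9	169-172
J9.0/9A	162
J9/9A	176-178
J9A/9.0	182
3'-tail	186-195
P1	1-2,6-7
P2	9-12,17-20
P3	24-27,115-118
P4	30-35,69-74
P5	38-39,65-66
P5a	46-50,55-59
P6	75-79,99-103
P6a	82-86,91-95
P7	107-111,152-156
P8	122-123,147-148
P8a	130-133,138-141
P9.0	159-161,183-185
P9A	163-165,179-181
P9	166-168,173-175
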