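name	positions
P-TL	1-6,11-16
TL	7-10
tether	17-25
P-TLR	26-27,49-50
TLR	28-33,44-48
P-TLR-inner	34-36,41-43
L-TLR	37-40
restrained	26-50
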