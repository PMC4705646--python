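kind	a	b	c	d	param
noe_SS	A181	U53			fmax=2,kmin=2,kmax=2
noe_SS	A181	A72			fmax=2,kmin=2,kmax=2
noe_SS	A183	C52			fmax=2,kmin=2,kmax=2
noe_SS	A183	G74			fmax=2,kmin=2,kmax=2
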