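kind	a	b	c	d	param
noe_SS	A39	C87			fmax=2,kmin=2,kmax=2
noe_SS	A39	G113			fmax=2,kmin=2,kmax=2
noe_SS	A40	C86			fmax=2,kmin=2,kmax=2
noe_SS	A40	G114			fmax=2,kmin=2,kmax=2
noe_SS	G116	C43			fmax=2,kmin=2,kmax=2
noe_SS	G116	G83			fmax=2,kmin=2,kmax=2
noe_SS	U117	G44			fmax=2,kmin=2,kmax=2
noe_SS	U117	C82			fmax=2,kmin=2,kmax=2
dihedral	C85:S	C86:P	C86:S	C87:P	K=50
dihedral	G84:S	C85:S	C86:P	C86:S	K=50
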