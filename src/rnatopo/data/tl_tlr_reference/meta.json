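{
 "name": "tl_tlr_reference",
 "description": "Tethered tetraloop / tetraloop-receptor reference system: GAAA tetraloop hairpin joined by an oligo-U tether to an 11-nt-receptor hairpin; residues 26-50 (the receptor hairpin) are held by backbone dihedral restraints (K = 50 kcal/mol) during production sampling.",
 "length": 50,
 "restrained_span": [
  26,
  50
 ],
 "dihedral_K": 50.0
}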