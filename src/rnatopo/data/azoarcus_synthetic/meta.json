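{
 "name": "azoarcus_synthetic",
 "description": "Synthetic reconstruction of the 195-nt Azoarcus group I ribozyme secondary structure (crystal numbering per PDB 1U6B chain B, residues 12-206). Helix architecture, pseudoknots, GAAA loops, 11-nt receptors, linker lengths and restraint-roster residue identities follow the published structure; helix fills and most linker identities are synthetic placeholders.",
 "length": 195,
 "numbering_offset": 11,
 "native_tl_tlr": [
  [
   "L2",
   "J8"
  ],
  [
   "L9",
   "J5"
  ]
 ],
 "tl_regions": [
  "L2",
  "L9",
  "L8",
  "L6",
  "L5",
  "5'-loop"
 ],
 "tlr_regions": [
  "J8",
  "J5",
  "J2/3"
 ]
}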