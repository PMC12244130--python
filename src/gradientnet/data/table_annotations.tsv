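gene_id	subgroup	symbol	germination_role	role_class
At2g28470	G1A	BGAL8	positive	promote
At4g26320	G1A	AGP13	positive	promote
At4g33720	G1A	CAPE3	unknown	none
At2g40330	G1A	PYL6	negative	inhibit
At2g15370	G1A	FUT5	unknown	none
At5g42180	G1A	PRX64	unknown	ambiguous
At1g09090	G1A	RBOHB	positive	promote
At4g20460	G1B	-	positive	promote
At4g35060	G1B	HMP39	unknown	none
At4g40010	G1B	SNRK2-7	negative	inhibit
At4g17340	G1B	TIP2;2	positive	promote
At1g15380	G1B	GLYI4	unknown	ambiguous
At2g44790	G1B	UCC2	negative	inhibit
At4g26220	G1B	-	unknown	none
At1g05260	G1B	PER3	unknown	ambiguous
At1g78090	G1B	-	unknown	ambiguous
At5g57560	G4A	XTH22	unknown	none
At5g64100	G4A	PRX69	negative	inhibit
At1g51170	G4A	-	unknown	none
At4g30080	G4A	ARF16	negative	inhibit
At1g19050	G4A	ARR7	positive	promote
At4g37900	G4A	GRDP2	negative	inhibit
At3g13380	G4A	BRL3	unknown	none
At2g34080	G4A	-	positive	promote
At4g03140	G4A	-	negative	inhibit
At2g28350	G4A	ARF10	negative	inhibit
At2g22420	G4A	PRX17	unknown	ambiguous
At1g23060	G4A	MDP40	unknown	none
At1g22880	G4A	CEL5	positive	promote
At2g23060	G4A	-	unknown	none
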