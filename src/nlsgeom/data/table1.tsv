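# Peptide-importin alpha complexes in the PDB, by site occupancy.
# minor_seq: printed P1'-P5' residues, left-aligned at P1'; '?' = not resolved.
# major_seq: printed P1-P6 residues.
pdb_id	category	peptide	minor_seq	major_seq	species
1Y2A	major_only	hPLSCR1		GKISKH	mouse
3BTR	major_only	Androgen receptor		RKLKKL	mouse
3OQS	major_only	CLIC4		AKKYRN	mouse
3RZ9	major_only	Ku80		AKKLKT	mouse
3RZX	major_only	Ku70		SKRPKV	mouse
3TPO	major_only	IBB		LKRRNV	mouse
3VE6	major_only	VEEVCP		AKKPKK	mouse
4BA3	major_only	a89		GKRKY	mouse
4HTV	major_only	BFDV Cap		RRRRRY	mouse
1BK6	two_copies	SV40Tag	KK??	KKKRKV	yeast
1EJL	two_copies	SV40Tag	KKRKV	KKKRKV	mouse
1Q1S	two_copies	SV40Tag pS112	KRKV	KKKRKV	mouse
1Q1T	two_copies	SV40Tag	KRKVE	KKKRKV	mouse
4B8O	two_copies	SV40Tag	KRKV	KKKRKV	rice
1EE4	two_copies	c-Myc	KRVKL	AKRVKL	yeast
1IQ1	two_copies	IBB	KRRNV	LKRRNV	mouse
2YNR	two_copies	b54	KRKR	GKRKRH	mouse
3L3Q	two_copies	PepTM	KRREA	KKKRRE	mouse
1IAL	bipartite	IBB	??	LKRRNV	mouse
1WA5	bipartite	IBB	RRRRD	AKRRNF	yeast
1EE5	bipartite	Nucleoplasmin	KRPAA	AKKKKL	yeast
1EJY	bipartite	Nucleoplasmin	KRPAA	AKKKK	mouse
3UL1	bipartite	Nucleoplasmin	KRPAA	AKKKKL	mouse
1PJM	bipartite	RB1	KRSAE	LKKLRG	mouse
1PJN	bipartite	N1N2	KRKTE	AKKSKG	mouse
2JDQ	bipartite	PB2 Influenza	KRDS	TKRIRM	human
3FEY	bipartite	NCBP1	RRRHS	HKRRKT	human
3KND	bipartite	TPX2	KRKHE	VKMIKT	mouse
3TPM	bipartite	MAL RPEL	KRK	LKRARL	mouse
3UKW	bipartite	Bimax1	KRPLE	RKRKRV	mouse
3UKX	bipartite	Bimax2	KRKRE	KKRRRL	mouse
3UKY	bipartite	CBP80 yeast	KRRG	PKRQRI	mouse
3UKZ	bipartite	CBP80 mouse	SRRRH	HKRRKT	mouse
3UL0	bipartite	CBP80 mut	SRRRH	HKRRKT	mouse
3UVU	bipartite	FEN1	KRKEP	KKKAKT	mouse
1UN0	minor_only	Nup2p	MRRKI		yeast
2C1M	minor_only	Nup50	KRVAE		mouse
2C1T	minor_only	Nup2p	KRVAD		yeast
3TJ3	minor_only	Nup50	KRNAE		human
2YNS	minor_only	b54	KRKRH		rice
4B8P	minor_only	a89	KRK?		rice
3Q5U	minor_only	hPLSCR4	IRKWN		mouse
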