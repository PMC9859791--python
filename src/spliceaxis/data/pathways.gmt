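NHEJ	non-homologous end joining	XRCC4	LIG4	XRCC5	XRCC6	PRKDC	DCLRE1C	NHEJ1	POLL	POLM	DNTT	MRE11	RAD50	FEN1
HR	homologous recombination	BRCA1	BRCA2	RAD51	RAD52	RAD54L	PALB2	XRCC2	XRCC3	BRIP1	BARD1
MMEJ	microhomology-mediated end joining	POLQ	PARP1	LIG1	LIG3	XRCC1	NBN
DNA_REPAIR	double-strand break repair (union)	BARD1	BRCA1	BRCA2	BRIP1	DCLRE1C	DNTT	FEN1	LIG1	LIG3	LIG4	MRE11	NBN	NHEJ1	PALB2	PARP1	POLL	POLM	POLQ	PRKDC	RAD50	RAD51	RAD52	RAD54L	XRCC1	XRCC2	XRCC3	XRCC4	XRCC5	XRCC6
SPLICEOSOME	spliceosome components incl. Hsp70 family	DDX5	EFTUD2	HSPA1A	HSPA1B	HSPA1L	HSPA6	HSPA8	LSM2	PRPF19	PRPF8	SF3A1	SF3B1	SNRNP200	SNRPA	SNRPB	SNRPD1	SRSF1	SRSF2	U2AF1	U2AF2
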