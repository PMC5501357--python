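accession	gene	tm	sp	ri
Q9H6X2	ANTXR1	1	1	D
Q8NCL9	APCDD1L	1	1	D
O00478	BTN3A3	1	1	I
Q5VU97	CACHD1	1	1	I
Q9NZQ7	CD274	1	1	I
Q8IZU8	DSEL	1	1	D
P30504	HLA-C	1	1	I
P20036	HLA-DPA1	1	1	I
P01903	HLA-DRA	1	1	I
P13747	HLA-E	1	1	I
P30511	HLA-F	1	1	I
P05362	ICAM1	1	1	I
Q14392	LRRC32	1	1	I
P17342	NPR3	1	1	D
Q9Y5H3	PCDHGA10	1	1	I
Q9BQ51	PDCD1LG2	1	1	I
Q15262	PTPRK	1	1	I
Q8WVN6	SECTM1	1	1	I
O15533	TAPBP	1	1	I
Q9BX59	TAPBPL	1	1	I
O15455	TLR3	1	1	I
Q9BXS4	TMEM59	1	1	I
P19320	VCAM1	1	1	I
Q5T3U5	ABCC10	1	0	D
Q9ULC5	ACSL5	1	0	I
Q6ICH7	ASPHD2	1	0	I
O75110	ATP9A	1	0	I
O43286	B4GALT5	1	0	I
Q10589	BST2	1	0	I
P04233	CD74	1	0	I
O15247	CLIC2	1	0	I
O95864	FADS2	1	0	D
Q14435	GALNT3	1	0	I
P36269	GGT5	1	0	I
Q01628	IFITM3	1	0	I
O15162	PLSCR1	1	0	I
O14684	PTGES	1	0	I
Q16647	PTGIS	1	0	I
Q9Y666	SLC12A7	1	0	I
P22732	SLC2A5	1	0	I
Q03518	TAP1	1	0	I
Q03519	TAP2	1	0	I
Q9P273	TENM3	1	0	D
Q8IWR1	TRIM59	1	0	I
O95183	VAMP5	1	0	I
Q86Y07	VRK2	1	0	I
Q86Y38	XYLT1	1	0	D
O14791	APOL1	0	1	I
P61769	B2M	0	1	I
P09871	C1S	0	1	I
P08603	CFH	0	1	I
P25774	CTSS	0	1	I
Q07325	CXCL9	0	1	I
Q96MK3	FAM20A	0	1	I
Q8IXL6	FAM20C	0	1	I
P02671	FGA	0	1	D
P02679	FGG	0	1	D
P13284	IFI30	0	1	I
P01579	IFNG	0	1	I
Q16363	LAMA4	0	1	I
Q08380	LGALS3BP	0	1	I
P35354	PTGS2	0	1	I
P05120	SERPINB2	0	1	I
P05155	SERPING1	0	1	I
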