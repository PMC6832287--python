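# Default S1-domain registry: 9 bacterial, 10 eukaryotic, 5 archaeal entries.
# Residue ranges are best-effort PF00575-style envelopes in author numbering;
# they are editable configuration, not code. Records sharing a `group` label
# describe the same protein from different organisms/depositions and are
# excluded from identity-extrema reporting.
# pdb_id	chain	start	end	kingdom	protein_name	group
1sro	A	1	76	bacteria	PNPase	pnpase
4aim	A	617	684	bacteria	PNPase	pnpase
1hh2	A	100	170	bacteria	NusA	nusa
5lm9	A	137	203	bacteria	NusA	nusa
5xgu	A	729	800	bacteria	RNase_R	-
5f6c	A	36	118	bacteria	RNase_E	-
2ix0	A	561	643	bacteria	RNase_II	-
3bzc	A	658	726	bacteria	Tex	-
2k4k	A	1	84	bacteria	GSP13	-
1q46	A	3	87	eukaryota	eIF2_alpha	-
1wi5	A	1	80	eukaryota	RRP5	-
2eqs	A	1	80	eukaryota	DHX8	-
2cqo	A	1	80	eukaryota	NOL_40kDa	-
2wp8	A	909	985	eukaryota	DIS3	-
6gmh	G	94	170	eukaryota	POLR2G	polr2g
6h25	I	936	1010	eukaryota	RRP44	-
6ir9	G	94	170	eukaryota	RNApolII_subunit	polr2g
4a3g	G	95	170	eukaryota	RPB7	-
2nn6	A	66	140	eukaryota	RRP40	-
2ba0	A	66	138	archaea	Rrp4	rrp4
2z0s	A	66	138	archaea	Rrp4	rrp4
3l7z	A	75	145	archaea	Csl4	-
1yz6	A	3	87	archaea	aIF2_alpha	aif2a
3aev	A	3	87	archaea	aIF2_alpha	aif2a
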