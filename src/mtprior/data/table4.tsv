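sample_id	variant	hf	locus	nt_var	aa_change	aa_var	disease_score	mitomap	genomes1k
A6665101A21D183510	11390A	0.861	MT-ND4	0.0002	Premature Stop Codon	0.01
A6665201A11D177110	3380A	0.967	MT-ND1	0.0003	R25Q	0.00	0.8800	MELAS	0.0004
AU377901A01D171910	10863A	0.909	MT-ND4	0.0003	S35N	0.00	0.7600
CM474301A01D171910	14918A	0.814	MT-CYB	0.0003	D58N	0.00	0.7100		0.0004
CM474301A01D171910	14985A	0.881	MT-CYB	0.0000	R80H	0.00	0.9000	Colorectal tumor	0.0017
CM534401A21D171910	11552C	0.819	MT-ND4	0.0000	S265P	0.00	0.8900
CM586101A01D165010	12814A	0.979	MT-ND5	0.0011	A160T	0.00	0.6900		0.0004
CM586401A01D165010	10854C	0.971	MT-ND4	0.0000	L32P	0.00	0.8500		0.0008
CM616401A11D165010	15243A	0.874	MT-CYB	0.0000	G166E	0.00	0.9000	HCM	0.0004
CM616501A11D165010	3946A	0.935	MT-ND1	0.0001	E214K	0.00	0.9100	MELAS	0.0012
D5653501A11D171910	9645A	0.861	MT-CO3	0.0000	A147T	0.00	0.8100		0.0004
D5654101A11D171910	4810A	0.9	MT-ND2	0.0000	Premature Stop Codon	0.00
D5693001A11D192410	6798A	0.866	MT-CO1	0.0000	V299M	0.00	0.7700
DMA0X901A11DA1521	3380A	0.799	MT-ND1	0.0003	R25Q	0.00	0.8800	MELAS	0.0004
DMA0X901A11DA1521	9790T	0.949	MT-CO3	0.0000	S195L	0.00	0.8300
DMA1D001A11DA15210	4537A	0.925	MT-ND2	0.0000	S23N	0.00	0.8200
DMA1DA01A11DA15210	8243A	0.954	MT-CO2	0.0000	E220K	0.00	0.7300		0.0008
DMA28501A11DA16V10	10233A	0.935	MT-ND3	0.0000	A59T	0.00	0.7700		0.0004
DMA28C01A11DA16V10	3380A	0.976	MT-ND1	0.0003	R25Q	0.00	0.8800	MELAS	0.0004
DMA28G01A11DA16V10	7623T	0.967	MT-CO2	0.0000	T13I	0.00	0.7700	LHON
G4629401A11D180610	4222C	0.95	MT-ND1	0.0000	S306P	0.00	0.7800
G4629501A11D171910	6744A	0.792	MT-CO1	0.0000	G281S	0.00	0.7700
G4631501A11D171910	11711A	0.792	MT-ND4	0.0003	A318T	0.00	0.7800		0.0037
G4632001A11D171910	9384A	0.893	MT-CO3	0.0000	D60N	0.00	0.7800		0.0008
G4658801A11D177110	4004C	0.768	MT-ND1	0.0000	M233T	0.00	0.4800
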