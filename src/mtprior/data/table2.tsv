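n_samples	variant	locus	nt_var	aa_change	aa_var	disease_score	mitomap	genomes1k
1	10747A	MT-ND4L	0.0000	L93Q	0	0.8781
1	6448A	MT-CO1	0.0000	P182H	0.0026	0.8325
1	7042C	MT-CO1	0.0000	V380A	0.0047	0.8044
1	15156G	MT-CYB	0.0003	Q137R	0.0005	0.9044
1	7632C	MT-CO2	0.0003	I16T	0.0018	0.4579
1	9104C	MT-ATP6	0.0007	F193S	0.0075	0.5168
1	14249A	MT-ND6	0.0016	A142V	0.0121	0.4498
1	8551C	MT-ATP6	0.0018	F9L	0.0042	0.7620		0.0008
1	3890A	MT-ND1	0.0000	R195Q	0	0.8184	PE/LS/OA
2	3733A	MT-ND1	0.0000	E143K	0	0.8360	LHON Top 14
9	3635A	MT-ND1	0.0000	S110N	0	0.7977	LHON Top 14
1	3733C	MT-ND1	0.0000	E143Q	0	0.8677	LHON
1	3922A	MT-ND1	0.0000	E206K	0	0.8939	Head/neck tumor
1	14495G	MT-ND6	0.0000	L60S	0	0.8616	LHON Top 14
1	10663C	MT-ND4L	0.0000	V65A	0	0.5776	LHON Top 14
1	14841G	MT-CYB	0.0000	N32S	0	0.8360	LHON helper mut.	0.0012
1	9655A	MT-CO3	0.0005	S150N	0.0029	0.7259	Thyroid tumor	0.0008
1	14459A	MT-ND6	0.0006	A72V	0.0183	0.8655	LDYT/LS/LHON Top 14	0.0008
4	14568T	MT-ND6	0.0009	G36S	0.0079	0.7311	LHON Top 14
15	3460A	MT-ND1	0.0014	A52T	0.0015	0.7629	LHON Top 14 (95 %)
2	4171A	MT-ND1	0.0016	L289M	0.0107	0.6809	LHON Top 14
2	14482A	MT-ND6	0.0024	M64I	0.0333	0.7923	LHON Top 14
41	11778A	MT-ND4	0.0025	R340H	0.0516	0.8534	LHON Top 14 (95 %)/PDY	0.0004
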