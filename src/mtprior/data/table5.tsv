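sample_id	variant	hf	locus	nt_var	aa_change	aa_var	disease_score	genomes1k
G4629410A	9447C	1/1	MT-CO3	0.0000	Y81H	0.0155	0.7772	0.0012
AY619710A	9106G	1/0.88	MT-ATP6	0.0004	T194A	0.0009	0.6682
F4680710A	8861T	1/1	MT-ATP6	0.0017	T112M	0.0276	0.5456
A6565710A	15434T	0.98/0.99	MT-CYB	0.0015	L230F	0.0016	0.7115	0.0008
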