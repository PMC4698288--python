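sample_id	variant	hf	locus	nt_var	aa_change	tumor_specific	aa_var	disease_score	genomes1k
EOC5	3380A	0.8	MT-ND1	0.0003	R25Q	+	0.00	0.8764	0.0004
EOC40	14969C	0.5	MT-CYB	0.0003	Y75H	+	0.00	0.8526	0.0004
EOC16	9837A	0.5	MT-CO3	0.0000	G211S	+	0.00	0.8379	0.0004
EOC20	15255C	0.8	MT-CYB	0.0000	V170A	+	0.00	0.8195	0.0004
EOC20	10696T	0.8	MT-ND4L	0.0000	A76V	+	0.01	0.7810
EOC14	6121C	0.5	MT-CO1	0.0007	I73T	+	0.00	0.7054	0.0004
EOC5	8412C	1.0	MT-ATP8	0.0023	M16T	-	0.03	0.6587	0.0008
EOC32	14249A	1.0	MT-ND6	0.0020	A142V	-	0.02	0.4498
EOC37	6691.A	0.5	MT-CO1	0	Frameshift	+	0
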