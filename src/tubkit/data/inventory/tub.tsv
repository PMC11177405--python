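name	ncbi_gene_id	gene_length_bp	exons	peptide_length_aa	ref_isotype	tub_class	chrom	subgenome	family	status
CsTUB6-A	104705499	2440	3	449	TUB6	I	8	G1	TUB	functional
CsTUB6-B	104735240	2488	3	449	TUB6	I	13	G2	TUB	functional
CsTUB6-C	104769465	2401	3	449	TUB6	I	20	G3	TUB	functional
CsTUB2-A	104780498	2355	3	449	TUB2/3	II	4	G1	TUB	functional
CsTUB2-B	104790913	2341	3	450	TUB2/3	II	6	G2	TUB	functional
CsTUB2-C	104711158	1989	3	450	TUB2/3	II	9	G3	TUB	functional
CsTUB3-A	104726871	2365	3	450	TUB2/3	II	11	G1	TUB	functional
CsTUB3-B	104762402	2080	3	451	TUB2/3	II	18	G2	TUB	functional
CsTUB3-C	104740363	2279	3	451	TUB2/3	II	2	G3	TUB	functional
CsTUB7-A	104700544	2319	3	449	TUB7	II	7	G1	TUB	functional
CsTUB7-B	104749926	2242	3	448	TUB7	II	16	G2	TUB	functional
CsTUB7-C	104786727	3249	3	449	TUB7	II	5	G3	TUB	functional
CsTUB8-A	104706681	1901	3	449	TUB8	II	8	G1	TUB	functional
CsTUB8-B	104736398	1827	3	449	TUB8	II	13	G2	TUB	functional
CsTUB4-C	104771594	3032	3	444	TUB4	III	20	G3	TUB	functional
CsTUB9-A	104722972	1878	3	444	TUB9	III	11	G1	TUB	functional
CsTUB9-B	104718249	1926	3	444	TUB9	III	10	G2	TUB	functional
CsTUB9-C	104731465	1892	3	444	TUB9	III	12	G3	TUB	functional
CsTUB1-A	104702324	2521	3	448	TUB1	IV	7	G1	TUB	functional
CsTUB1-B	104751460	2502	3	448	TUB1	IV	16	G2	TUB	functional
CsTUB5-A	104740697	2660	3	449	TUB5	IV	14	G1	TUB	functional
CsTUB5-B	104776116	3217	3	449	TUB5	IV	3	G2	TUB	functional
CsTUB5-C	104756348	3828	3	450	TUB5	IV	17	G3	TUB	functional
CsTUB-A	104781875	2245	3	446	TUB	III-like	4	G1	TUB	functional
CsTUB-B	104792233	2427	3	446	TUB	III-like	6	G2	TUB	functional
CsTUB-C	104786080	2352	3	446	TUB	III-like	5	G3	TUB	functional
CsTUB1p-C	NA	NA	NA	NA	TUB1	IV	NA	G3	TUB	pseudogene
CsTUB3p-C	NA	NA	NA	NA	TUB2/3	II	2	G3	TUB	pseudogene
CsTUB4p-A	NA	NA	NA	NA	TUB4	III	NA	G1	TUB	pseudogene
CsTUB4p-B	NA	NA	NA	NA	TUB4	III	NA	G2	TUB	pseudogene
CsTUB4p-C	NA	NA	NA	NA	TUB4	III	NA	G3	TUB	pseudogene
CsTUB9p-A	NA	NA	NA	NA	TUB9	III	NA	G1	TUB	pseudogene
CsTUB9p-B	NA	NA	NA	NA	TUB9	III	NA	G2	TUB	pseudogene
CsTUB9p-C	NA	NA	NA	NA	TUB9	III	NA	G3	TUB	pseudogene
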