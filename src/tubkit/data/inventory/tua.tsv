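name	ncbi_gene_id	gene_length_bp	exons	peptide_length_aa	ref_isotype	tub_class	chrom	subgenome	family	status
CsTUA2-A	104742538	2266	4	450	TUA2/4/6	I	14	G1	TUA	functional
CsTUA2-B	104777925	2266	4	450	TUA2/4/6	I	3	G2	TUA	functional
CsTUA2-C	104758270	2138	4	450	TUA2/4/6	I	17	G3	TUA	functional
CsTUA4-A	104765838	2219	4	451	TUA2/4/6	I	19	G1	TUA	functional
CsTUA4-B	104784567	2193	4	451	TUA2/4/6	I	1	G2	TUA	functional
CsTUA4-C	104746364	2246	4	451	TUA2/4/6	I	15	G3	TUA	functional
CsTUA6-A	104703779	2267	4	450	TUA2/4/6	I	7	G1	TUA	functional
CsTUA6-B	104752837	8668	4	450	TUA2/4/6	I	16	G2	TUA	functional
CsTUA6-C	104714511	2598	4	450	TUA2/4/6	I	9	G3	TUA	functional
CsTUA1-A	104700952	2319	5	450	TUA1	II	7	G1	TUA	functional
CsTUA1-Un	104773561	5961	5	444	TUA1	II	Scaff00574	unplaced	TUA	functional
CsTUA3-A	104706313	2150	5	450	TUA3	II	8	G1	TUA	functional
CsTUA3-B	104736043	2041	5	450	TUA3	II	13	G2	TUA	functional
CsTUA3-C	104770349	2079	5	450	TUA3	II	20	G3	TUA	functional
CsTUA5p-A	104706312	840	2	NA	TUA5	II	8	G1	TUA	pseudogene
CsTUA5-B	104736047	2114	5	450	TUA5	II	13	G2	TUA	functional
CsTUA5-C	104770351	2052	5	450	TUA5	II	20	G3	TUA	functional
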