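name	ncbi_gene_id	gene_length_bp	exons	peptide_length_aa	ref_isotype	tub_class	chrom	subgenome	family	status
CsTUG1-A	104699727	3344	10	474	TUG1	1	7	G1	TUG	functional
CsTUG1-B	104749225	3194	10	474	TUG1	1	16	G2	TUG	functional
CsTUG1-C	104788465	3135	10	474	TUG1	1	5	G3	TUG	functional
CsTUG2-A	104708550	2813	10	474	TUG2	2	8	G1	TUG	functional
CsTUG2-B	104734567	2835	10	474	TUG2	2	13	G2	TUG	functional
CsTUG2-C	104768758	2737	10	474	TUG2	2	20	G3	TUG	functional
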