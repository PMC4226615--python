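# Published per-sample variant-concordance counts: MPS call sets vs the Sanger truth panel
# PGM datasets were called with the platform vendor pipeline; MiSeq datasets with a GATK-based pipeline
sample	platform	prep	n_truth	n_detected	n_false_negative	n_extra
1	PGM	ion_shear	33	32	1	1
1	PGM	covaris	33	32	1	1
1	PGM	nebnext	33	32	1	1
1	MiSeq	truseq_covaris	33	33	0	1
1	MiSeq	truseq_nebnext	33	33	0	1
1	MiSeq	nextera_xt	33	33	0	1
2	PGM	ion_shear	13	11	2	1
2	PGM	covaris	13	12	1	1
2	PGM	nebnext	13	12	1	1
2	MiSeq	truseq_covaris	13	13	0	1
2	MiSeq	truseq_nebnext	13	13	0	1
2	MiSeq	nextera_xt	13	13	0	1
4	PGM	ion_shear	33	32	1	0
4	PGM	covaris	33	31	2	0
4	PGM	nebnext	33	31	2	0
4	MiSeq	truseq_covaris	33	33	0	0
4	MiSeq	truseq_nebnext	33	33	0	0
4	MiSeq	nextera_xt	33	33	0	0
9	PGM	ion_shear	36	35	1	2
9	PGM	covaris	36	35	1	2
9	PGM	nebnext	36	35	1	2
9	MiSeq	truseq_covaris	36	36	0	3
9	MiSeq	truseq_nebnext	36	36	0	2
9	MiSeq	nextera_xt	36	36	0	2
14	PGM	ion_shear	57	56	1	0
14	PGM	covaris	57	56	1	0
14	PGM	nebnext	57	56	1	0
14	MiSeq	truseq_covaris	57	57	0	1
14	MiSeq	truseq_nebnext	57	57	0	1
14	MiSeq	nextera_xt	57	57	0	0
21	PGM	ion_shear	42	40	2	0
21	PGM	covaris	42	41	1	0
21	PGM	nebnext	42	41	1	0
21	MiSeq	truseq_covaris	42	41	1	0
21	MiSeq	truseq_nebnext	42	41	1	0
21	MiSeq	nextera_xt	42	41	1	0
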