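# Published per-method minor-allele fractions (percent) of heteroplasmic variants
sample	variant	platform	prep	fraction_pct
1	m.12071T>C	PGM	ion_shear	12.2
1	m.12071T>C	PGM	covaris	12.2
1	m.12071T>C	PGM	nebnext	12.1
1	m.12071T>C	MiSeq	truseq_covaris	12
1	m.12071T>C	MiSeq	truseq_nebnext	12
1	m.12071T>C	MiSeq	nextera_xt	23
2	m.7989T>C	PGM	ion_shear	17.1
2	m.7989T>C	PGM	covaris	14.7
2	m.7989T>C	PGM	nebnext	14.1
2	m.7989T>C	MiSeq	truseq_covaris	19
2	m.7989T>C	MiSeq	truseq_nebnext	19
2	m.7989T>C	MiSeq	nextera_xt	13
9	m.9769T>C	PGM	ion_shear	9.7
9	m.9769T>C	PGM	covaris	9
9	m.9769T>C	PGM	nebnext	8.5
9	m.9769T>C	MiSeq	truseq_covaris	8
9	m.9769T>C	MiSeq	truseq_nebnext	8
9	m.9769T>C	MiSeq	nextera_xt	8
9	m.10866T>C	PGM	ion_shear	7.3
9	m.10866T>C	PGM	covaris	6
9	m.10866T>C	PGM	nebnext	6.4
9	m.10866T>C	MiSeq	truseq_covaris	7
9	m.10866T>C	MiSeq	truseq_nebnext	9
9	m.10866T>C	MiSeq	nextera_xt	7
9	m.8207C>T	PGM	ion_shear	1.5
9	m.8207C>T	PGM	covaris	1.3
9	m.8207C>T	PGM	nebnext	1.5
9	m.8207C>T	MiSeq	truseq_covaris	2
9	m.8207C>T	MiSeq	truseq_nebnext	1
9	m.8207C>T	MiSeq	nextera_xt	2
14	m.5609T>C	PGM	ion_shear	4
14	m.5609T>C	PGM	covaris	8
14	m.5609T>C	PGM	nebnext	4.8
14	m.5609T>C	MiSeq	truseq_covaris	4
14	m.5609T>C	MiSeq	truseq_nebnext	4
14	m.5609T>C	MiSeq	nextera_xt	4
14	m.7453G>A	PGM	ion_shear	52
14	m.7453G>A	PGM	covaris	55
14	m.7453G>A	PGM	nebnext	53
14	m.7453G>A	MiSeq	truseq_covaris	53
14	m.7453G>A	MiSeq	truseq_nebnext	54
14	m.7453G>A	MiSeq	nextera_xt	56
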