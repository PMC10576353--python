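snp	chr	pos	closest_gene	cis_trans	effect_allele	other_allele	eaf_exposure	beta_exposure	se_exposure	n_exposure	eaf_outcome	beta_outcome	se_outcome
rs2012444	3	12375956	PPARG	trans	T	C	0.13	0.11	0.01	20436	0.12	-0.01	0.01
rs77878271	8	82395535	FABP4	cis	A	G	0.97	0.26	0.04	20436	0.98	0.05	0.03
rs79389622	9	126081452	CRB2	trans	A	G	0.01	-0.59	0.10	20436	0.00	-0.07	0.08
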