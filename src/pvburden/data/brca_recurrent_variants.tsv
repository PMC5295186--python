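gene	hgvs_c	effect	allele_count	maf_percent	type
BRCA1	NM_007294.3:c.68_69delAG	p.Glu23Valfs*17	29	0.024	Founder
BRCA1	NM_007294.3:c.5266dupC	p.Gln1756Profs*74	19	0.016	Founder
BRCA1	NM_007294.3:c.181T>G	p.Cys61Gly	8	0.0067	Founder
BRCA1	NM_007294.3:c.4035delA	p.Glu1346Lysfs*20	5	0.0041	Founder
BRCA1	NM_007294.3:c.1687C>T	p.Gln563*	5	0.0041	Founder
BRCA2	NM_000059.3:c.5946delT	p.Ser1982Argfs*22	32	0.027	Founder
BRCA2	NM_000059.3:c.3847_3848delGT	p.Val1283Lysfs*2	11	0.011	Recurrent
BRCA2	NM_000059.3:c.658_659delGT	p.Val220Ilefs*4	6	0.0061	Recurrent
BRCA2	NM_000059.3:c.7480C>T	p.Arg2494*	6	0.0050	Founder
BRCA2	NM_000059.3:c.3545_3546delTT	p.Phe1182*	4	0.0033	Recurrent
BRCA2	NM_000059.3:c.3599_3600delGT	p.Cys1200*	4	0.0033	Recurrent
BRCA2	NM_000059.3:c.5576_5579delTTAA	p.Ile1859Lysfs*3	4	0.0033	Recurrent
BRCA2	NM_000059.3:c.7069_7070delCT	p.Leu2357Valfs*2	4	0.0033	Recurrent
BRCA2	NM_000059.3:c.9118-2A>G	splice_acceptor	4	0.0033	Recurrent
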