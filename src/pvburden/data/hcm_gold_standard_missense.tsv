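gene	hgvs_c	effect	classification	maf_percent	low_an	non_pass
MYBPC3	NM_000256.3:c.772G>A	p.Glu258Lys	Pathogenic	0.0039	1	0
MYH7	NM_000257.2:c.2389G>A	p.Ala797Thr	Pathogenic	0.0033	0	0
MYBPC3	NM_000256.3:c.1504C>T	p.Arg502Trp	Pathogenic	0.0025	0	0
MYH7	NM_000257.2:c.2167C>T	p.Arg723Cys	Pathogenic	0.0025	0	0
TNNI3	NM_000363.4:c.485G>A	p.Arg162Gln	Pathogenic	0.0025	0	0
MYH7	NM_000257.2:c.1988G>A	p.Arg663His	Pathogenic	0.0016	0	0
MYBPC3	NM_000256.3:c.1484G>A	p.Arg495Gln	Pathogenic	0.00083	0	0
MYL2	NM_000432.3:c.173G>A	p.Arg58Gln	Pathogenic	0.00083	0	0
MYL2	NM_000432.3:c.64G>A	p.Glu22Lys	Pathogenic	0.00083	0	0
TNNI3	NM_000363.4:c.433C>T	p.Arg145Trp	Pathogenic	0.00083	0	0
MYH7	NM_000257.2:c.2609G>A	p.Arg870His	Pathogenic	0.00082	0	1
TNNT2	NM_001001430.1:c.274C>T	p.Arg92Trp	Pathogenic	0.00082	0	0
TNNI3	NM_000363.4:c.433C>G	p.Arg145Gly	Pathogenic	0.00080	0	0
MYBPC3	NM_000256.3:c.1351G>C	p.Glu451Gln	Pathogenic	0	0	0
MYBPC3	NM_000256.3:c.1505G>A	p.Arg502Gln	Pathogenic	0	0	0
MYBPC3	NM_000256.3:c.2265C>A	p.Asn755Lys	Pathogenic	0	0	0
MYH7	NM_000257.2:c.1207C>T	p.Arg403Trp	Pathogenic	0	0	0
MYH7	NM_000257.2:c.1208G>A	p.Arg403Gln	Pathogenic	0	0	0
MYH7	NM_000257.2:c.1357C>T	p.Arg453Cys	Pathogenic	0	0	0
MYH7	NM_000257.2:c.1750G>C	p.Gly584Arg	Pathogenic	0	0	0
MYH7	NM_000257.2:c.1816G>A	p.Val606Met	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2146G>A	p.Gly716Arg	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2155C>T	p.Arg719Trp	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2156G>A	p.Arg719Gln	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2167C>G	p.Arg723Gly	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2221G>T	p.Gly741Trp	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2717A>G	p.Asp906Gly	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2722C>G	p.Leu908Val	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2770G>A	p.Glu924Lys	Pathogenic	0	0	0
MYH7	NM_000257.2:c.2788G>A	p.Glu930Lys	Pathogenic	0	0	0
MYH7	NM_000257.2:c.4135G>A	p.Ala1379Thr	Pathogenic	0	0	0
MYH7	NM_000257.2:c.438G>T	p.Lys146Asn	Pathogenic	0	0	0
MYH7	NM_000257.2:c.767G>A	p.Gly256Glu	Pathogenic	0	0	0
TNNI3	NM_000363.4:c.470C>T	p.Ala157Val	Pathogenic	0	0	0
TNNI3	NM_000363.4:c.557G>A	p.Arg186Gln	Pathogenic	0	0	0
TNNI3	NM_000363.4:c.575G>A	p.Arg192His	Pathogenic	0	0	0
TNNT2	NM_001001430.1:c.236T>A	p.Ile79Asn	Pathogenic	0	0	0
TNNT2	NM_001001430.1:c.275G>A	p.Arg92Gln	Pathogenic	0	0	0
TNNT2	NM_001001430.1:c.421C>T	p.Arg141Trp	Pathogenic	0	0	0
TPM1	NM_000366.5:c.523G>A	p.Asp175Asn	Pathogenic	0	0	0
TPM1	NM_000366.5:c.688G>A	p.Asp230Asn	Pathogenic	0	0	0
MYBPC3	NM_000256.3:c.2686G>A	p.Val896Met	Likely benign	1.28	1	0
MYBPC3	NM_000256.3:c.833G>A	p.Gly278Glu	Likely benign	0.29	1	0
TNNI3	NM_000363.4:c.244C>T	p.Pro82Ser	Likely benign	0.28	0	0
MYBPC3	NM_000256.3:c.565G>A	p.Val189Ile	Likely benign	0.27	0	0
MYBPC3	NM_000256.3:c.3413G>A	p.Arg1138His	Likely benign	0.13	0	0
MYBPC3	NM_000256.3:c.1519G>A	p.Gly507Arg	Likely benign	0.068	0	0
MYBPC3	NM_000256.3:c.3004C>T	p.Arg1002Trp	Likely benign	0.067	0	0
TNNI3	NM_000363.4:c.235C>T	p.Arg79Cys	Likely benign	0.043	0	0
MYBPC3	NM_000256.3:c.1564G>A	p.Ala522Thr	Likely benign	0.039	0	0
MYBPC3	NM_000256.3:c.440C>T	p.Pro147Leu	Likely benign	0.038	1	0
MYH7	NM_000257.2:c.3981C>A	p.Asn1327Lys	Likely benign	0.010	0	0
MYBPC3	NM_000256.3:c.1147C>G	p.Leu383Val	Likely benign	0.0089	0	0
MYBPC3	NM_000256.3:c.842G>A	p.Arg281Gln	Likely benign	0.0070	1	0
MYBPC3	NM_000256.3:c.1633C>A	p.Leu545Met	Likely benign	0.0034	0	0
MYBPC3	NM_000256.3:c.1246G>A	p.Gly416Ser	Likely benign	0.0029	0	0
MYBPC3	NM_000256.3:c.2063C>A	p.Thr688Lys	Likely benign	0.0019	1	0
MYBPC3	NM_000256.3:c.3142C>T	p.Arg1048Cys	Likely benign	0.0017	0	0
TNNT2	NM_001001430.1:c.805A>T	p.Asn269Tyr	Likely benign	0.0017	1	0
MYBPC3	NM_000256.3:c.2410C>A	p.Leu804Met	Likely benign	0	0	0
MYH7	NM_000257.2:c.321T>G	p.Asp107Glu	Likely benign	0	0	0
MYH7	NM_000257.2:c.4555A>T	p.Ser1519Cys	Likely benign	0	0	0
MYH7	NM_000257.2:c.8A>C	p.Asp3Ala	Likely benign	0	0	0
TNNI3	NM_000363.4:c.244C>A	p.Pro82Thr	Likely benign	0	0	0
TNNI3	NM_000363.4:c.253T>A	p.Leu85Met	Likely benign	0	0	0
TNNI3	NM_000363.4:c.257C>A	p.Ala86Asp	Likely benign	0	0	0
TNNT2	NM_001001430.1:c.682C>G	p.Gln228Glu	Likely benign	0	0	0
MYBPC3	NM_000256.3:c.706A>G	p.Ser236Gly	Benign	10.79	0	0
MYBPC3	NM_000256.3:c.472G>A	p.Val158Met	Benign	9.04	1	0
TNNT2	NM_001001430.1:c.758A>G	p.Lys253Arg	Benign	5.07	0	0
MYH7	NM_000257.2:c.4472C>G	p.Ser1491Cys	Benign	0.75	0	0
MYBPC3	NM_000256.3:c.977G>A	p.Arg326Gln	Benign	0.55	0	0
MYBPC3	NM_000256.3:c.1144C>T	p.Arg382Trp	Benign	0.42	0	0
MYBPC3	NM_000256.3:c.2498C>T	p.Ala833Val	Benign	0.22	0	0
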