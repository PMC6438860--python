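cdna_hgvs	protein_hgvs	source	splicing_prediction	splicing_confirmed	location	sift	polyphen	grantham_published	affects_hbond_within	affects_hbond_other	hbond_other_partner	affects_polar_contacts
c.319C > G	p.Leu107Val	published	IMPACTS SPLICING - confirmed in vitro	yes	Coiled coil domain alpha helix 1	0.04 (affects protein function)	0.074 (benign)	32	-	-		-
c.341T > A	p.Ile114Asn	this_study	No impact on splicing	no	Coiled coil domain alpha helix 1	0.00 (affects protein function)	0.963	149	Y	N		N
c.413C > A	p.Thr138Lys	published	Potential alteration of splicing	no	Coiled coil tip alpha helix 3	0.05 (tolerated)	1	78	Y	N		N
c.581C > A	p.Ala194Glu	published	Potential alteration of splicing	no	Coiled coil domain alpha helix 6	0.02 (affects protein function)	1	91	Y	N		N
c.590T > C	p.Leu197Pro	published	Potential alteration of splicing	no	Coiled coil domain alpha helix 6	0.00 (affects protein function)	1	98	N	N		Y
c.646G > C	p.Ala216Pro	published	Potential alteration of splicing	no	Coiled coil domain alpha helix 6	0.00 (affects protein function)	1	27	N	N		Y
c.781G > C	p.Gly261Arg	published	No impact on splicing	no	Flexible loop	0.01 (affects protein function)	0.999	125	Y	Y	PRPF8	N
c.862C > T	p.Arg288Trp	published	Potential alteration of splicing	no	Nop domain alpha helix 12	0.00 (affects protein function)	1	101	Y	N		N
c.871G > C	p.Ala291Pro	published	No impact on splicing	no	Nop domain alpha helix 12	0.09 (tolerated)	1	27	Y	N		Y
c.895T > C	p.Cys299Arg	published	No impact on splicing	no	Nop domain alpha helix 12	0.00 (affects protein function)	1	180	Y	N		N
c.896G > A	p.Cys299Tyr	published	Potential alteration of splicing	no	Nop domain alpha helix 12	0.00 (affects protein function)	0.997	194	Y	N		N
c.1222C > T	p.Arg408Trp	published	Potential alteration of splicing	no	C-terminal domain	0.00 (affects protein function). Low confidence prediction	1	101	N	Y	PRPF6	N
c.1373A > T	p.Gln458Leu	published	Most probably affecting splicing	no	C-terminal domain	0.00 (affects protein function). Low confidence prediction	0.931 (possibly damaging)	113	-	-		-
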