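gene	chromosome	nt_change	aa_change	rsid	n_carriers	n_cohort	prediction	evidence	population_note
ABCB4	7	c.G2363A	p.R788Q	rs8187801	3	33	driver	reported	ExAC_AFR
ATM	11	c.C7375G	p.R2459G	rs730881383	1	33	driver	reported	ExAC_OTH
ATM	11	c.C7468T	p.L2490F	rs753262623	1	33	driver	reported	ExAC_SAS
CD36	7	c.G1016T	p.G339V	rs146027667	1	33	driver	known	ExAC_OTH
CHD8	14	c.C871T	p.L291F	rs192989929	1	33	driver	reported	ExAC_OTH/ExAC_AMR
DPYD	1	c.A2846T	p.D949V	rs67376798	1	33	driver	reported	ExAC_NFE
EPHA1	7	c.C2371T	p.R791C	rs766301333	1	33	driver	reported	ExAC_NFE
ERBB3	12	c.G2167C	p.V723L	rs189789018	1	33	driver	known	ExAC_AMR
ESR1	6	c.G1138C	p.E380Q	rs1057519827	1	33	driver	known	all populations similar
MLH1	3	c.A1129G	p.K377E	rs35001569	1	33	driver	reported	ExAC_NFE
MSH3	5	c.T2732G	p.L911W	rs41545019	2	33	driver	reported	ExAC_NFE
NOTCH1	9	c.G2983A	p.G995S	rs868369610	1	33	driver	reported	all populations similar
NOTCH4	6	c.G2504T	p.G835V	rs9267835	2	33	driver	known	ExAC_AFR/ExAC_AMR
STAT6	12	c.C1069T	p.R357W	rs776930978	1	33	driver	reported	all populations similar
TP53	17	c.G338T	p.G113V	rs121912656	1	33	driver	reported	ExAC_EAS
TP53	17	c.T215A	p.L72Q	rs1057519997	1	33	driver	reported	all populations similar
UPF3B	X	c.G1082A	p.R361H	rs143538947	1	33	driver	reported	ExAC_AFR
CBLB	3	c.G1972A	p.G658S	.	1	33	driver	new	.
PRPF8	17	c.G4153T	p.V1385F	.	1	33	driver	new	.
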