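id	name	compartment	role
ligA[e]	LPS-like ligand A	e	ligand
ligB[e]	RNA-like ligand B	e	ligand
ligC[e]	peptidoglycan-like ligand C	e	ligand
orphL[e]	orphan invader ligand	e	ligand
shedA[e]	shed receptor-A ectodomain	e	protein
atp[c]	ATP	c	metabolite
adp[c]	ADP	c	metabolite
gtp[c]	GTP	c	metabolite
gdp[c]	GDP	c	metabolite
sigA[c]	ligand-receptor A complex	c	complex
sigB[c]	ligand-receptor B complex	c	complex
sigC[c]	ligand-receptor C complex	c	complex
aA[c]	activated adaptor (branch A)	c	protein
aB[c]	activated adaptor (branch B)	c	protein
aC[c]	activated adaptor (branch C)	c	protein
kA[c]	active kinase complex (branch A)	c	kinase
kB[c]	active kinase complex (branch B)	c	kinase
kC[c]	active kinase complex (branch C)	c	kinase
tA[c]	terminal kinase (branch A)	c	kinase
tB[c]	terminal kinase (branch B)	c	kinase
tC[c]	terminal kinase (branch C)	c	kinase
lx[c]	futile-cycle intermediate X	c	protein
ly[c]	futile-cycle intermediate Y	c	protein
nfkbA[n]	nuclear NF-kB	n	protein
ap1B[n]	nuclear AP-1	n	protein
crebA[n]	nuclear CREB	n	protein
irf[n]	nuclear IRF complex	n	complex
ros[v]	reactive oxygen species	v	metabolite
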