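id	formula	lb	ub	gpr	rclass
EX_ligA[e]	ligA[e] <=>	-1000	1000		exchange
EX_ligB[e]	ligB[e] <=>	-1000	1000		exchange
EX_ligC[e]	ligC[e] <=>	-1000	1000		exchange
EX_atp[c]	atp[c] <=>	-1000	1000		exchange
EX_gtp[c]	gtp[c] <=>	-1000	1000		exchange
SK_adp[c]	adp[c] ->	0	1000		sink
SK_gdp[c]	gdp[c] ->	0	1000		sink
RECA_BIND	ligA[e] -> sigA[c]	0	1000	101	binding
RECB_BIND	ligB[e] -> sigB[c]	0	1000	102	binding
RECC_BIND	ligC[e] -> sigC[c]	0	1000	103	binding
ORPH_BIND	orphL[e] -> sigB[c]	0	1000	701	binding
SHED_A	sigA[c] -> shedA[e]	0	1000		transport
DEG_SIGA	sigA[c] ->	0	1000		sink
DEG_SIGB	sigB[c] ->	0	1000		sink
DEG_SIGC	sigC[c] ->	0	1000		sink
ADAPT_A	sigA[c] + atp[c] -> aA[c] + adp[c]	0	1000	201 or 202	core
ADAPT_B	sigB[c] + atp[c] -> aB[c] + adp[c]	0	1000	201 or 202	core
ADAPT_C	sigC[c] + atp[c] -> aC[c] + adp[c]	0	1000	201 or 202	core
KIN_A	aA[c] + atp[c] -> kA[c] + adp[c]	0	1000	301 and 302	core
KIN_B	aB[c] + atp[c] -> kB[c] + adp[c]	0	1000	301 and 302	core
KIN_C	aC[c] + atp[c] -> kC[c] + adp[c]	0	1000	301 and 302	core
CASC_A	kA[c] + atp[c] -> tA[c] + adp[c]	0	1000	401 or 402 or 403	core
CASC_B	kB[c] + atp[c] -> tB[c] + adp[c]	0	1000	401 or 402 or 403	core
CASC_C	kC[c] + atp[c] -> tC[c] + adp[c]	0	1000	401 or 402 or 403	core
NFKB_ACT	tA[c] -> nfkbA[n]	0	1000	501	core
AP1_ACT	tB[c] -> ap1B[n]	0	1000	502	core
CREB_ACT	kA[c] -> crebA[n]	0	1000	401 or 402	core
IRF_COMPLEX	tA[c] + tC[c] -> irf[n]	0	1000		core
ROS_SYN	kB[c] + gtp[c] -> ros[v] + gdp[c]	0	1000	601	core
DM_NFKB[n]	nfkbA[n] ->	0	1000		demand
DM_AP1[n]	ap1B[n] ->	0	1000		demand
DM_CREB[n]	crebA[n] ->	0	1000		demand
DM_IRF[n]	irf[n] ->	0	1000		demand
DM_ROS[v]	ros[v] ->	0	1000		demand
LOOP_F	lx[c] -> ly[c]	0	10		core
LOOP_R	ly[c] -> lx[c]	0	10		core
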