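gene_id	symbol	description
101	TLRA	receptor A (single gene)
102	TLRB	receptor B (single gene)
103	TLRC	receptor C (single gene)
201	ADPT1	adaptor isoform 1
202	ADPT2	adaptor isoform 2
301	KINC1	kinase complex subunit 1
302	KINC2	kinase complex subunit 2
401	CASC1	cascade kinase isoform 1
402	CASC2	cascade kinase isoform 2
403	CASC3	cascade kinase isoform 3
501	NFKB1	NF-kB activating factor
502	JUNB	AP-1 activating factor
601	GTPS1	ROS branch GTPase
701	ORPHR	orphan ligand receptor
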