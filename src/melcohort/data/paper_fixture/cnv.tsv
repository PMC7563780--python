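sample_id	gene	direction	is_driver
P001	CDKN2A	deletion	true
P001	PTEN	deletion	true
P002	MYC	amplification	true
P004	PTEN	deletion	true
P005	PTEN	deletion	true
P006	PTEN	deletion	true
P007	CDKN2A	deletion	true
P009	EGFR	amplification	true
P010	MYC	amplification	true
P016	CDKN2A	deletion	true
P016	EGFR	amplification	true
P017	EGFR	amplification	true
P018	CDKN2A	deletion	true
P018	PTEN	deletion	true
P019	PTEN	deletion	true
P020	CDKN2A	deletion	true
P023	PTEN	deletion	true
P024	CDKN2A	deletion	true
P026	MYC	amplification	true
P029	PTEN	deletion	true
P030	CDKN2A	deletion	true
P031	MYC	amplification	true
P035	CDKN2A	deletion	true
P036	MYC	amplification	true
P040	CDKN2A	deletion	true
P040	MYC	amplification	true
P043	CDK4	amplification	true
P044	CDKN2A	deletion	true
P045	CDKN2A	deletion	true
P046	CDKN2A	deletion	true
P046	MYC	amplification	true
P047	EGFR	amplification	true
P047	KIT	amplification	true
P047	PDGFRA	amplification	true
P047	PTEN	deletion	true
P048	CDK4	amplification	true
P048	EGFR	amplification	true
P048	PTEN	deletion	true
P049	EGFR	amplification	true
P049	KIT	amplification	true
P049	PDGFRA	amplification	true
P050	PTEN	deletion	true
P050	RICTOR	amplification	true
P051	CDKN2A	deletion	true
P052	KIT	amplification	true
P052	PDGFRA	amplification	true
P052	PTEN	deletion	true
P053	CDK4	amplification	true
P053	MYC	amplification	true
P054	MYC	amplification	true
P054	RICTOR	amplification	true
P055	KIT	amplification	true
P055	PDGFRA	amplification	true
P056	CDK4	amplification	true
P057	CCND2	amplification	true
P058	CDKN2A	deletion	true
P058	CHEK2	deletion	true
P059	CCND2	amplification	true
P059	PTEN	deletion	true
P059	TP53	deletion	true
P060	CHEK2	deletion	true
P060	PTEN	deletion	true
P060	TP53	deletion	true
P061	MYC	amplification	true
P062	CCND2	amplification	true
P063	CCND2	amplification	true
P063	CDKN2A	deletion	true
P064	CHEK2	deletion	true
P064	MYC	amplification	true
P065	CCND2	amplification	true
P066	MYC	amplification	true
P067	MYC	amplification	true
P068	MYC	amplification	true
P069	MYC	amplification	true
P070	MYC	amplification	true
P071	MYC	amplification	true
P072	MYC	amplification	true
P073	MYC	amplification	true
P081	MYC	amplification	true
P082	CDKN2A	deletion	true
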