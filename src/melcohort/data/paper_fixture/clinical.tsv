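sample_id	subtype	ici_regimen	recist_response	braf_meki_pretreated
P001	cutaneous	combined	PD	true
P002	cutaneous	combined	PD	true
P003	cutaneous	combined	PD	true
P004	cutaneous	combined	PD	true
P005	cutaneous	combined	PD	true
P006	cutaneous	combined	PD	true
P007	cutaneous	combined	PD	true
P008	cutaneous	combined	PD	true
P009	cutaneous	combined	PD	true
P010	cutaneous	combined	PD	true
P011	cutaneous	combined	PD	true
P012	cutaneous	combined	PD	true
P013	cutaneous	combined	PD	false
P014	cutaneous	combined	PD	false
P015	cutaneous	combined	PD	false
P016	cutaneous	combined	PD	false
P017	cutaneous	combined	PD	false
P018	cutaneous	combined	PD	false
P019	cutaneous	combined	PD	false
P020	cutaneous	combined	PD	false
P021	cutaneous	combined	SD	true
P022	cutaneous	combined	SD	false
P023	cutaneous	combined	SD	false
P024	cutaneous	combined	SD	false
P025	cutaneous	combined	SD	false
P026	cutaneous	combined	SD	false
P027	cutaneous	combined	SD	false
P028	cutaneous	combined	PR	true
P029	cutaneous	combined	PR	false
P030	cutaneous	combined	PR	false
P031	cutaneous	combined	PR	false
P032	cutaneous	combined	PR	false
P033	cutaneous	combined	PR	false
P034	cutaneous	combined	PR	false
P035	cutaneous	combined	PR	false
P036	cutaneous	combined	PR	false
P037	cutaneous	combined	PR	false
P038	cutaneous	combined	PR	false
P039	cutaneous	none	not_applicable	false
P040	cutaneous	none	not_applicable	false
P041	cutaneous	none	not_applicable	false
P042	cutaneous	none	not_applicable	false
P043	acral	combined	PD	true
P044	acral	combined	PD	false
P045	acral	combined	PD	false
P046	acral	combined	PD	false
P047	acral	combined	PD	false
P048	acral	combined	PD	false
P049	acral	combined	PD	false
P050	acral	combined	PD	false
P051	acral	combined	PD	false
P052	acral	combined	SD	false
P053	acral	combined	SD	false
P054	acral	combined	PR	false
P055	acral	combined	PR	false
P056	acral	none	not_applicable	false
P057	mucosal	combined	PD	true
P058	mucosal	combined	PD	false
P059	mucosal	combined	PD	false
P060	mucosal	combined	PD	false
P061	mucosal	combined	PD	false
P062	mucosal	combined	SD	false
P063	mucosal	combined	PR	false
P064	mucosal	combined	PR	false
P065	mucosal	none	not_applicable	false
P066	uveal	combined	PD	false
P067	uveal	anti_pd1	PD	false
P068	uveal	anti_pd1	PD	false
P069	uveal	anti_pd1	PD	false
P070	uveal	anti_pd1	PD	false
P071	uveal	anti_pd1	PD	false
P072	uveal	anti_pd1	SD	false
P073	uveal	anti_pd1	PR	false
P074	occult	anti_pd1	PD	true
P075	occult	anti_pd1	PD	true
P076	occult	anti_pd1	PD	false
P077	occult	anti_pd1	PD	false
P078	occult	anti_pd1	PD	false
P079	occult	anti_pd1	SD	false
P080	occult	anti_pd1	PR	false
P081	occult	anti_pd1	PR	false
P082	occult	none	not_applicable	false
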