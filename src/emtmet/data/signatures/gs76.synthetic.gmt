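GS76_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	CDH1	GSA001	GSA002	GSA003	GSA004	GSA005	GSA006	GSA007	GSA008	GSA009	GSA010	GSA011	GSA012	GSA013	GSA014	GSA015	GSA016	GSA017	GSA018	GSA019	GSA020	GSA021	GSA022	GSA023	GSA024	GSA025	GSA026	GSA027	GSA028	GSA029	GSA030	GSA031	GSA032	GSA033	GSA034	GSA035	GSA036	GSA037	GSA038	GSA039	GSA040	GSA041	GSA042	GSA043	GSA044	GSA045	GSA046	GSA047	GSA048	GSA049	GSA050	GSA051	GSA052	GSA053	GSA054	GSA055	GSA056	GSA057	GSA058	GSA059	GSA060	GSA061	GSA062	GSA063	GSA064	GSA065	GSA066	GSA067	GSA068	GSA069	GSA070	GSA071	GSA072	GSA073	GSA074	GSA075
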