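KS_EPITHELIAL_CELLLINE_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	CDH1	KSE001	KSE002	KSE003	KSE004	KSE005	KSE006	KSE007	KSE008	KSE009	KSE010	KSE011	KSE012	KSE013	KSE014	KSE015	KSE016	KSE017	KSE018	KSE019	KSE020	KSE021	KSE022	KSE023	KSE024	KSE025	KSE026	KSE027	KSE028	KSE029	KSE030	KSE031	KSE032	KSE033	KSE034	KSE035	KSE036	KSE037	KSE038	KSE039	KSE040	KSE041	KSE042	KSE043	KSE044	KSE045	KSE046	KSE047	KSE048	KSE049	KSE050	KSE051	KSE052	KSE053	KSE054	KSE055	KSE056	KSE057	KSE058	KSE059	KSE060	KSE061	KSE062	KSE063	KSE064	KSE065	KSE066	KSE067	KSE068	KSE069	KSE070	KSE071	KSE072	KSE073	KSE074	KSE075	KSE076	KSE077	KSE078	KSE079	KSE080	KSE081	KSE082	KSE083	KSE084	KSE085	KSE086	KSE087	KSE088	KSE089	KSE090	KSE091	KSE092	KSE093	KSE094	KSE095	KSE096	KSE097	KSE098	KSE099	KSE100	KSE101	KSE102	KSE103	KSE104	KSE105	KSE106	KSE107	KSE108	KSE109	KSE110	KSE111	KSE112	KSE113	KSE114	KSE115	KSE116	KSE117	KSE118	KSE119	KSE120	KSE121	KSE122	KSE123	KSE124	KSE125	KSE126	KSE127	KSE128	KSE129
KS_MESENCHYMAL_CELLLINE_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	KSM001	KSM002	KSM003	KSM004	KSM005	KSM006	KSM007	KSM008	KSM009	KSM010	KSM011	KSM012	KSM013	KSM014	KSM015	KSM016	KSM017	KSM018	KSM019	KSM020	KSM021	KSM022	KSM023	KSM024	KSM025	KSM026	KSM027	KSM028	KSM029	KSM030	KSM031	KSM032	KSM033	KSM034	KSM035	KSM036	KSM037	KSM038	KSM039	KSM040	KSM041	KSM042	KSM043	KSM044	KSM045	KSM046	KSM047	KSM048	KSM049	KSM050	KSM051	KSM052	KSM053	KSM054	KSM055	KSM056	KSM057	KSM058	KSM059	KSM060	KSM061	KSM062	KSM063	KSM064	KSM065	KSM066	KSM067	KSM068	KSM069	KSM070	KSM071	KSM072	KSM073	KSM074	KSM075	KSM076	KSM077	KSM078	KSM079	KSM080	KSM081	KSM082	KSM083	KSM084	KSM085	KSM086	KSM087	KSM088
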