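KS_EPITHELIAL_TUMOR_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	KTE001	KTE002	KTE003	KTE004	KTE005	KTE006	KTE007	KTE008	KTE009	KTE010	KTE011	KTE012	KTE013	KTE014	KTE015	KTE016	KTE017	KTE018	KTE019	KTE020	KTE021	KTE022	KTE023	KTE024	KTE025	KTE026	KTE027	KTE028	KTE029	KTE030	KTE031	KTE032	KTE033	KTE034	KTE035	KTE036	KTE037	KTE038	KTE039	KTE040	KTE041	KTE042	KTE043	KTE044	KTE045	KTE046	KTE047	KTE048	KTE049	KTE050	KTE051	KTE052	KTE053	KTE054	KTE055	KTE056	KTE057	KTE058	KTE059	KTE060	KTE061	KTE062	KTE063	KTE064	KTE065	KTE066	KTE067	KTE068	KTE069	KTE070	KTE071	KTE072	KTE073	KTE074	KTE075	KTE076	KTE077	KTE078	KTE079	KTE080	KTE081	KTE082	KTE083	KTE084	KTE085	KTE086	KTE087	KTE088	KTE089	KTE090	KTE091	KTE092	KTE093	KTE094	KTE095	KTE096	KTE097	KTE098	KTE099	KTE100	KTE101	KTE102	KTE103	KTE104	KTE105	KTE106	KTE107	KTE108	KTE109	KTE110	KTE111	KTE112	KTE113	KTE114	KTE115	KTE116	KTE117	KTE118	KTE119	KTE120	KTE121	KTE122	KTE123	KTE124	KTE125	KTE126	KTE127	KTE128	KTE129	KTE130	KTE131	KTE132	KTE133	KTE134	KTE135	KTE136	KTE137	KTE138	KTE139	KTE140	KTE141	KTE142	KTE143	KTE144	KTE145
KS_MESENCHYMAL_TUMOR_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	KTM001	KTM002	KTM003	KTM004	KTM005	KTM006	KTM007	KTM008	KTM009	KTM010	KTM011	KTM012	KTM013	KTM014	KTM015	KTM016	KTM017	KTM018	KTM019	KTM020	KTM021	KTM022	KTM023	KTM024	KTM025	KTM026	KTM027	KTM028	KTM029	KTM030	KTM031	KTM032	KTM033	KTM034	KTM035	KTM036	KTM037	KTM038	KTM039	KTM040	KTM041	KTM042	KTM043	KTM044	KTM045	KTM046	KTM047	KTM048	KTM049	KTM050	KTM051	KTM052	KTM053	KTM054	KTM055	KTM056	KTM057	KTM058	KTM059	KTM060	KTM061	KTM062	KTM063	KTM064	KTM065	KTM066	KTM067	KTM068	KTM069	KTM070	KTM071	KTM072	KTM073	KTM074	KTM075	KTM076	KTM077	KTM078	KTM079	KTM080	KTM081	KTM082	KTM083	KTM084	KTM085	KTM086	KTM087	KTM088	KTM089	KTM090	KTM091	KTM092	KTM093	KTM094	KTM095	KTM096	KTM097	KTM098	KTM099	KTM100	KTM101	KTM102	KTM103	KTM104	KTM105	KTM106	KTM107	KTM108	KTM109	KTM110	KTM111	KTM112	KTM113	KTM114	KTM115	KTM116	KTM117	KTM118	KTM119	KTM120	KTM121	KTM122	KTM123	KTM124	KTM125	KTM126	KTM127	KTM128	KTM129	KTM130	KTM131	KTM132	KTM133	KTM134	KTM135	KTM136	KTM137	KTM138	KTM139	KTM140	KTM141	KTM142	KTM143	KTM144	KTM145	KTM146	KTM147	KTM148	KTM149	KTM150	KTM151	KTM152	KTM153	KTM154	KTM155	KTM156	KTM157	KTM158	KTM159	KTM160	KTM161	KTM162	KTM163	KTM164	KTM165	KTM166	KTM167	KTM168	KTM169	KTM170
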