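HALLMARK_EMT_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	HEM001	HEM002	HEM003	HEM004	HEM005	HEM006	HEM007	HEM008	HEM009	HEM010	HEM011	HEM012	HEM013	HEM014	HEM015	HEM016	HEM017	HEM018	HEM019	HEM020	HEM021	HEM022	HEM023	HEM024	HEM025	HEM026	HEM027	HEM028	HEM029	HEM030	HEM031	HEM032	HEM033	HEM034	HEM035	HEM036	HEM037	HEM038	HEM039	HEM040	HEM041	HEM042	HEM043	HEM044	HEM045	HEM046	HEM047	HEM048	HEM049	HEM050	HEM051	HEM052	HEM053	HEM054	HEM055	HEM056	HEM057	HEM058	HEM059	HEM060	HEM061	HEM062	HEM063	HEM064	HEM065	HEM066	HEM067	HEM068	HEM069	HEM070	HEM071	HEM072	HEM073	HEM074	HEM075	HEM076	HEM077	HEM078	HEM079	HEM080	HEM081	HEM082	HEM083	HEM084	HEM085	HEM086	HEM087	HEM088	HEM089	HEM090	HEM091	HEM092	HEM093	HEM094	HEM095	HEM096	HEM097	HEM098	HEM099	HEM100	HEM101	HEM102	HEM103	HEM104	HEM105	HEM106	HEM107	HEM108	HEM109	HEM110	HEM111	HEM112	HEM113	HEM114	HEM115	HEM116	HEM117	HEM118	HEM119	HEM120	HEM121	HEM122	HEM123	HEM124	HEM125	HEM126	HEM127	HEM128	HEM129	HEM130	HEM131	HEM132	HEM133	HEM134	HEM135	HEM136	HEM137	HEM138	HEM139	HEM140	HEM141	HEM142	HEM143	HEM144	HEM145	HEM146	HEM147	HEM148	HEM149	HEM150	HEM151	HEM152	HEM153	HEM154	HEM155	HEM156	HEM157	HEM158	HEM159	HEM160	HEM161	HEM162	HEM163	HEM164	HEM165	HEM166	HEM167	HEM168	HEM169	HEM170	HEM171	HEM172	HEM173	HEM174	HEM175	HEM176	HEM177	HEM178	HEM179	HEM180	HEM181	HEM182	HEM183	HEM184	HEM185	HEM186	HEM187	HEM188	HEM189	HEM190	HEM191	HEM192	HEM193	HEM194	HEM195	HEM196	HEM197	HEM198	HEM199	HEM200
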