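HALLMARK_GLYCOLYSIS_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	HGL001	HGL002	HGL003	HGL004	HGL005	HGL006	HGL007	HGL008	HGL009	HGL010	HGL011	HGL012	HGL013	HGL014	HGL015	HGL016	HGL017	HGL018	HGL019	HGL020	HGL021	HGL022	HGL023	HGL024	HGL025	HGL026	HGL027	HGL028	HGL029	HGL030	HGL031	HGL032	HGL033	HGL034	HGL035	HGL036	HGL037	HGL038	HGL039	HGL040	HGL041	HGL042	HGL043	HGL044	HGL045	HGL046	HGL047	HGL048	HGL049	HGL050	HGL051	HGL052	HGL053	HGL054	HGL055	HGL056	HGL057	HGL058	HGL059	HGL060	HGL061	HGL062	HGL063	HGL064	HGL065	HGL066	HGL067	HGL068	HGL069	HGL070	HGL071	HGL072	HGL073	HGL074	HGL075	HGL076	HGL077	HGL078	HGL079	HGL080	HGL081	HGL082	HGL083	HGL084	HGL085	HGL086	HGL087	HGL088	HGL089	HGL090	HGL091	HGL092	HGL093	HGL094	HGL095	HGL096	HGL097	HGL098	HGL099	HGL100	HGL101	HGL102	HGL103	HGL104	HGL105	HGL106	HGL107	HGL108	HGL109	HGL110	HGL111	HGL112	HGL113	HGL114	HGL115	HGL116	HGL117	HGL118	HGL119	HGL120	HGL121	HGL122	HGL123	HGL124	HGL125	HGL126	HGL127	HGL128	HGL129	HGL130	HGL131	HGL132	HGL133	HGL134	HGL135	HGL136	HGL137	HGL138	HGL139	HGL140	HGL141	HGL142	HGL143	HGL144	HGL145	HGL146	HGL147	HGL148	HGL149	HGL150	HGL151	HGL152	HGL153	HGL154	HGL155	HGL156	HGL157	HGL158	HGL159	HGL160	HGL161	HGL162	HGL163	HGL164	HGL165	HGL166	HGL167	HGL168	HGL169	HGL170	HGL171	HGL172	HGL173	HGL174	HGL175	HGL176	HGL177	HGL178	HGL179	HGL180	HGL181	HGL182	HGL183	HGL184	HGL185	HGL186	HGL187	HGL188	HGL189	HGL190	HGL191	HGL192	HGL193	HGL194	HGL195	HGL196	HGL197	HGL198	HGL199	HGL200
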