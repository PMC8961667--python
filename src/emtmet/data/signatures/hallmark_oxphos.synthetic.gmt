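HALLMARK_OXPHOS_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	HOX001	HOX002	HOX003	HOX004	HOX005	HOX006	HOX007	HOX008	HOX009	HOX010	HOX011	HOX012	HOX013	HOX014	HOX015	HOX016	HOX017	HOX018	HOX019	HOX020	HOX021	HOX022	HOX023	HOX024	HOX025	HOX026	HOX027	HOX028	HOX029	HOX030	HOX031	HOX032	HOX033	HOX034	HOX035	HOX036	HOX037	HOX038	HOX039	HOX040	HOX041	HOX042	HOX043	HOX044	HOX045	HOX046	HOX047	HOX048	HOX049	HOX050	HOX051	HOX052	HOX053	HOX054	HOX055	HOX056	HOX057	HOX058	HOX059	HOX060	HOX061	HOX062	HOX063	HOX064	HOX065	HOX066	HOX067	HOX068	HOX069	HOX070	HOX071	HOX072	HOX073	HOX074	HOX075	HOX076	HOX077	HOX078	HOX079	HOX080	HOX081	HOX082	HOX083	HOX084	HOX085	HOX086	HOX087	HOX088	HOX089	HOX090	HOX091	HOX092	HOX093	HOX094	HOX095	HOX096	HOX097	HOX098	HOX099	HOX100	HOX101	HOX102	HOX103	HOX104	HOX105	HOX106	HOX107	HOX108	HOX109	HOX110	HOX111	HOX112	HOX113	HOX114	HOX115	HOX116	HOX117	HOX118	HOX119	HOX120	HOX121	HOX122	HOX123	HOX124	HOX125	HOX126	HOX127	HOX128	HOX129	HOX130	HOX131	HOX132	HOX133	HOX134	HOX135	HOX136	HOX137	HOX138	HOX139	HOX140	HOX141	HOX142	HOX143	HOX144	HOX145	HOX146	HOX147	HOX148	HOX149	HOX150	HOX151	HOX152	HOX153	HOX154	HOX155	HOX156	HOX157	HOX158	HOX159	HOX160	HOX161	HOX162	HOX163	HOX164	HOX165	HOX166	HOX167	HOX168	HOX169	HOX170	HOX171	HOX172	HOX173	HOX174	HOX175	HOX176	HOX177	HOX178	HOX179	HOX180	HOX181	HOX182	HOX183	HOX184	HOX185	HOX186	HOX187	HOX188	HOX189	HOX190	HOX191	HOX192	HOX193	HOX194	HOX195	HOX196	HOX197	HOX198	HOX199	HOX200
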