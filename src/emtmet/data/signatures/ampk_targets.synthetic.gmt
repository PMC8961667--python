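AMPK_TARGETS_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	AMP001	AMP002	AMP003	AMP004	AMP005	AMP006	AMP007	AMP008	AMP009	AMP010	AMP011	AMP012	AMP013	AMP014	AMP015	AMP016	AMP017	AMP018	AMP019	AMP020	AMP021	AMP022	AMP023	AMP024	AMP025	AMP026	AMP027	AMP028	AMP029	AMP030	AMP031	AMP032	AMP033
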