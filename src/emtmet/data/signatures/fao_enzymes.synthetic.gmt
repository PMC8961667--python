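FAO_ENZYMES_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	FAO001	FAO002	FAO003	FAO004	FAO005	FAO006	FAO007	FAO008	FAO009	FAO010	FAO011	FAO012	FAO013	FAO014
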