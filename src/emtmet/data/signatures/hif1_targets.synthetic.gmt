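HIF1_TARGETS_SYNTHETIC	synthetic placeholder gene list (not a real signature; override with a real GMT)	HIF001	HIF002	HIF003	HIF004	HIF005	HIF006	HIF007	HIF008	HIF009	HIF010	HIF011	HIF012	HIF013	HIF014	HIF015	HIF016	HIF017	HIF018	HIF019	HIF020	HIF021	HIF022	HIF023
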