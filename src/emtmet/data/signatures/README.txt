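Bundled signature files
=======================

These GMT files are SYNTHETIC placeholders.  They carry the correct
cardinalities of the published signatures they stand in for (76 genes for
the 76GS list, 218 cell-line and 315 tumor genes for the KS epithelial /
mesenchymal split, 33 AMPK targets, 23 HIF1-alpha targets, 14 FAO enzyme
genes, 200-gene hallmark sets) but their members are prefix-coded dummy
symbols (HEM###, KSE###, ...), not real HGNC genes.  The single real symbol
is CDH1, which anchors the 76GS weighting and belongs to the epithelial
list.

They exist so that the scoring pipeline, the synthetic-cohort generator and
the test suite run self-contained.  For analyses of real expression data,
override every slot with the genuine gene sets (MSigDB hallmark collections
and the published EMT / AMPK / HIF1 / FAO lists) via
`load_registry(directory=...)` or a registry YAML config.
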