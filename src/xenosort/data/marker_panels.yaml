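# Cell-type marker panels for graft fate profiling (editable).
# Gene symbols follow human nomenclature; edit or extend freely and pass
# the file to `xenosort profile --markers`.
pluripotency: [NANOG, POU5F1]
nsc: [SOX2, CXCR4]
neuronal: [ENO2, MAP2]
astrocyte: [GFAP, AQP4, SLC1A3, S100B, CD44]
oligodendrocyte: [OLIG1, OLIG2]
safety: [PODXL, PRODH]
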