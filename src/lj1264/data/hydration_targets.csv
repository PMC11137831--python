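species,c4_o_ow,experimental_dg,ff_calculated_dg,experimental_source
H2PO4-,73,-111.06,-111.11,measured
HPO4^2-,22,-315.69,-315.64,extrapolated
PO4^3-,-18,-660.85,-660.92,measured
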