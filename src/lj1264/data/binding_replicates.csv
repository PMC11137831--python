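metal,species,experimental_dg,rep1,rep2,rep3,c4_metal_o
Ca2+,H2PO4-,-1.92,-1.89,-1.97,-2.02,104.00
Ca2+,HPO4^2-,-3.70,-3.54,-3.47,-3.61,-69.50
Ca2+,PO4^3-,-8.81,-8.69,-8.34,-8.56,-257.00
Mg2+,H2PO4-,-1.73,-1.75,-1.65,-1.73,174.90
Mg2+,HPO4^2-,-3.86,-3.63,-3.52,-3.49,-64.40
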