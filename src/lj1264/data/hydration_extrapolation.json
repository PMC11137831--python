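{
  "slope": 1.0763,
  "intercept": -22.984,
  "note": "linear extrapolation of quantum-chemistry-calculated hydration free energies (x) against experimental values (y), used to estimate the missing experimental value for the doubly deprotonated phosphate"
}
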