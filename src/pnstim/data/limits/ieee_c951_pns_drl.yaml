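# IEEE C95.1-2019 dosimetric reference limits: in-situ electric field for
# peripheral-nerve (extremities/"other tissue") protection, restricted
# environment, 5-mm line-average convention. Peak values.
name: ieee_c951_pns_drl
quantity: internal_E
unit: V/m
convention: peak
citation: >-
  Transcribed from IEEE C95.1-2019 (C95.6-2002 lineage), in-situ electric
  field DRL for peripheral nerve, f_e = 3350 Hz breakpoint.
segments:
  - {f_low: 1.0, f_high: 3350.0, c: 2.1}
  - {f_low: 3350.0, f_high: 1.0e6, a: 6.2686567164e-4, p: 1.0}
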