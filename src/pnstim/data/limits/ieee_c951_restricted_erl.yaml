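# IEEE C95.1-2019 exposure reference levels, magnetic flux density (rms),
# head and torso, persons in restricted environments; the constant segment
# is extended to 1 MHz for band coverage (electrostimulation regime).
name: ieee_c951_restricted_erl
quantity: external_B
unit: T
convention: rms
citation: >-
  Transcribed from IEEE C95.1-2019 (electrostimulation ERLs inherited from
  C95.6-2002), head-and-torso magnetic flux density, restricted environment.
segments:
  - {f_low: 20.3, f_high: 759.0, a: 0.163, p: -1.0}
  - {f_low: 759.0, f_high: 1.0e6, c: 2.1475625823e-4}
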