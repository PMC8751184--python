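# ICNIRP 2010 basic restrictions for occupational exposure: internal
# electric field (rms), all tissues of head and body (PNS-relevant band).
name: icnirp2010_occupational_br
quantity: internal_E
unit: V/m
convention: rms
citation: >-
  Transcribed from the ICNIRP 2010 low-frequency guidelines (Health Phys
  99:818-836), Table 2, occupational basic restrictions.
segments:
  - {f_low: 1.0, f_high: 3000.0, c: 0.8}
  - {f_low: 3000.0, f_high: 1.0e7, a: 2.7e-4, p: 1.0}
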