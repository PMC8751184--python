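# ICNIRP 2010 low-frequency guidelines: reference levels for occupational
# exposure, magnetic flux density (rms), 25 Hz - 10 MHz portion.
name: icnirp2010_occupational_rl
quantity: external_B
unit: T
convention: rms
citation: >-
  Transcribed from the ICNIRP 2010 low-frequency guidelines (Health Phys
  99:818-836), Table 4, occupational magnetic flux density reference levels.
segments:
  - {f_low: 25.0, f_high: 300.0, c: 1.0e-3}
  - {f_low: 300.0, f_high: 3000.0, a: 0.3, p: -1.0}
  - {f_low: 3000.0, f_high: 1.0e7, c: 1.0e-4}
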