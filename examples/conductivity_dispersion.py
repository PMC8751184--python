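"""Tissue conductivity over the electrostimulation band.

Evaluates the 4-Cole-Cole dispersion model for the packaged tissues and
prints the effective conductivity at a few frequencies.  Conductivity rises
with frequency (dispersion), which is why the induced-field solve is
repeated per frequency in the threshold sweep.
"""

import numpy as np

from pnstim import cole_cole_sigma, load_cole_cole_table

table = load_cole_cole_table()
freqs = [300.0, 1e3, 1e4, 1e5, 1e6]

print(f"{'tissue':8s}" + "".join(f"{f:>12.0f} Hz" for f in freqs))
for name in sorted(table):
    sig = [cole_cole_sigma(table[name], f) for f in freqs]
    print(f"{name:8s}" + "".join(f"{s:12.4g} " for s in sig))
print("\nValues are conduction-only conductivities in S/m; muscle is the "
      "best conductor,\ndry skin the worst, and every curve is "
      "non-decreasing in frequency.")
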