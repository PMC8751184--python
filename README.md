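# pnstim

Multi-scale peripheral-nerve electrostimulation dosimetry for uniform
magnetic-field exposure (300 Hz – 1 MHz), for researchers who evaluate human
exposure-protection limits (ICNIRP guidelines, IEEE C95.1) against computed
nerve-activation thresholds.

A time-varying magnetic field **B** induces an electric field in the body,

&nbsp;&nbsp;&nbsp;&nbsp;**E** = −∇φ − jω**A**₀,&nbsp;&nbsp;&nbsp;
∇·σ(∇φ + jω**A**₀) = 0,

solved here with the scalar-potential finite-difference (SPFD) method on a
voxel volume conductor with 4-Cole-Cole tissue conductivities.  The induced
field drives a myelinated axon through its quasi-potential (the line
integral of **E** along the fiber) in a compartmental cable model with
CRRSS (Chiu–Ritchie–Rogart–Stagg–Sweeney) sodium + leak nodal dynamics:

&nbsp;&nbsp;&nbsp;&nbsp;C dVₖ/dt + I_ion,k = Σⱼ (V_j − V_k)/R_kj + Σⱼ (V_e,j − V_e,k)/R_kj.

Activation thresholds over pulse width w follow the strength–duration law
I = b(1 + C/w), with rheobase b and chronaxie C; the membrane multipliers
(C×6.0, G_Na×8.0, G_l×0.25 for perception; C×8.5, G_Na×4.5, G_l×0.25 for
the uncomfortable response) calibrate the model against experimentally
derived targets (b = 4.8 / 7.3 V/m, C = 360 μs).  Licensed anatomical voxel
models are not redistributable, so a layered elliptical torso phantom
(skin / fat / muscle / bone) stands in for the anatomy; thresholds computed
on it are qualitatively, not anatomically, meaningful.

## Worked example

```
python examples/strength_duration.py
```

```
  width (us)  threshold (V/m)    fit (V/m)
          50           25.946       26.560
         100           14.989       14.892
         300            7.432        7.113
        1000            4.294        4.391

rheobase  b = 3.22 V/m (experimental target 4.8 V/m)
chronaxie C = 362 us (experimental target 360 us)
```

Short pulses require stronger internal fields; the fit condenses the curve
into (b, C).  The chronaxie of the calibrated perception model matches the
360 μs experimental value; the uniform-field rheobase sits below the
in-situ experimental target — docs/methods.md discusses why.  Other
examples: `conductivity_dispersion.py` (tissue σ(f)),
`cylinder_dosimetry.py` (solver vs. the π f B r closed form),
`phantom_hotspots.py` (field map → averaging → hotspot seeding), and
`threshold_margins.py` (end-to-end thresholds vs. limit curves).

A thin CLI mirrors the library: `pnstim phantom|dosimetry|sdfit|run|report`.

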