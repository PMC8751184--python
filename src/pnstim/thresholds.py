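"""Threshold search, strength–duration fitting, and calibration.

The activation threshold of a fiber is found by bisection on the stimulus
amplitude; the strength–duration (S-D) protocol measures thresholds for
bipolar rectangular pulse pairs over a set of pulse widths and fits the
classical hyperbolic law

    I(w) = b (1 + C / w)

whose parameters are the rheobase ``b`` (asymptotic long-pulse threshold)
and chronaxie ``C`` (width at which threshold doubles).  The calibration
routine searches the response multipliers of the CRRSS axon model so that
the fitted (b, C) match experimentally derived targets — 4.8 V/m / 360 μs
for perception in the trunk, with the uncomfortable response a 1.5× higher
rheobase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .axon import AxonParams, detect_activation, simulate
from .fibers import FiberPath, curved_fiber, sample_quasipotential, uniform_field_fiber

__all__ = [
    "StimulusWaveform",
    "SDCurve",
    "RheobaseConversion",
    "find_threshold",
    "fit_sd",
    "sd_protocol",
    "convert_rheobase",
    "calibrate_params",
    "population_thresholds",
    "scale_threshold_inverse_diameter",
    "DEFAULT_WIDTHS_S",
    "SD_TARGETS",
]

#: pulse widths of the experimental S-D protocol (s)
DEFAULT_WIDTHS_S = tuple(w * 1e-6 for w in
                         (20, 50, 100, 150, 200, 300, 500, 700, 1000))
#: inter-phase interval of the bipolar pulse pair (s)
DEFAULT_INTERVAL_S = 300e-6

#: experimentally derived calibration targets: rheobase (V/m, internal field)
#: and chronaxie (s) per response class
SD_TARGETS = {
    "perceptual": {"rheobase_vm": 4.8, "chronaxie_s": 360e-6},
    "uncomfortable": {"rheobase_vm": 7.3, "chronaxie_s": 360e-6},
}


@dataclass(frozen=True)
class StimulusWaveform:
    """Dimensionless stimulus time course (unit amplitude).

    ``bipolar_pulse``: a positive rectangular phase of width ``width_s``,
    a zero gap of ``interval_s``, then the mirrored negative phase — the
    waveform used in the S-D experiments.  ``sinusoid``: ``cycles`` periods
    at ``frequency_hz``.
    """

    kind: str                      # 'bipolar_pulse' | 'sinusoid'
    width_s: float | None = None
    interval_s: float = DEFAULT_INTERVAL_S
    frequency_hz: float | None = None
    cycles: int | None = None

    def __post_init__(self):
        if self.kind == "bipolar_pulse":
            if not self.width_s or self.width_s <= 0:
                raise ValueError("bipolar_pulse needs width_s > 0")
        elif self.kind == "sinusoid":
            if not self.frequency_hz or self.frequency_hz <= 0:
                raise ValueError("sinusoid needs frequency_hz > 0")
        else:
            raise ValueError(f"unknown waveform kind {self.kind!r}")

    @classmethod
    def bipolar_pulse(cls, width_s: float,
                      interval_s: float = DEFAULT_INTERVAL_S):
        return cls(kind="bipolar_pulse", width_s=width_s, interval_s=interval_s)

    @classmethod
    def sinusoid(cls, frequency_hz: float, cycles: int | None = None):
        if cycles is None:
            # at least 10 cycles or 2 ms of drive, whichever is longer
            cycles = max(10, math.ceil(2e-3 * frequency_hz))
        return cls(kind="sinusoid", frequency_hz=frequency_hz, cycles=cycles)

    @property
    def stim_duration_s(self) -> float:
        if self.kind == "bipolar_pulse":
            return 2.0 * self.width_s + self.interval_s
        return self.cycles / self.frequency_hz

    def recommended_dt(self) -> float:
        if self.kind == "bipolar_pulse":
            return min(1e-6, self.width_s / 20.0)
        # resolve both the carrier (50 samples/period) and the membrane
        return min(2e-6, 1.0 / (50.0 * self.frequency_hz))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "bipolar_pulse":
            w, gap = self.width_s, self.interval_s
            out = np.zeros_like(t)
            out[(t >= 0) & (t < w)] = 1.0
            out[(t >= w + gap) & (t < 2 * w + gap)] = -1.0
            return out
        out = np.sin(2 * np.pi * self.frequency_hz * t)
        out[t >= self.stim_duration_s] = 0.0
        return out


@dataclass
class SDCurve:
    """Strength–duration data and hyperbolic fit I = b(1 + C/w)."""

    widths_s: np.ndarray
    thresholds: np.ndarray
    rheobase: float
    chronaxie_s: float
    residual: float
    units: str = "V/m"

    def predict(self, w):
        return self.rheobase * (1.0 + self.chronaxie_s / np.asarray(w, float))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"width_s": self.widths_s,
                             "threshold": self.thresholds,
                             "fit": self.predict(self.widths_s)})


@dataclass
class RheobaseConversion:
    """External-rheobase to internal-field conversion, E_th = E_sim · (dB/dt)_th / (dB/dt)_sim.

    Exactly one of the four fields may be None; :func:`convert_rheobase`
    fills it from the other three.
    """

    dBdt_th: float | None = None   # T/s, measured external rheobase
    dBdt_sim: float | None = None  # T/s, simulated exposure
    E_sim: float | None = None     # V/m, simulated internal field
    E_th: float | None = None      # V/m, internal-field rheobase


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------


def find_threshold(path: FiberPath, params: AxonParams,
                   waveform: StimulusWaveform, rel_tol: float = 0.01, *,
                   bounds: tuple[float, float] = (1e-3, 1e3),
                   dt: float | None = None, tail_s: float = 3e-3,
                   level_mv: float = 80.0, n_detect: int = 4,
                   history: list | None = None) -> float:
    """Activation threshold amplitude by bisection on the drive scale.

    The returned value is the upper (activating) bound of the final bracket,
    ``(upper − lower)/lower ≤ rel_tol``, in the units of the fiber's
    quasi-potential basis (V/m for a uniform-field fiber, mT for a fiber
    sampled from a solved exposure field at the 1 mT basis).
    """
    if path.ve is None:
        raise ValueError("fiber has no quasi-potential; sample it first")
    if dt is None:
        dt = waveform.recommended_dt()
    duration = waveform.stim_duration_s + tail_s
    n_detect = min(n_detect, path.n_nodes)

    def activates(a: float) -> bool:
        tr = simulate(path, params, waveform, dt=dt, duration=duration,
                      amplitude=a)
        act = detect_activation(tr, level_mv=level_mv, n_nodes=n_detect)
        if history is not None:
            history.append((a, act))
        return act

    lo, hi = bounds
    # log-spaced outward bracketing from amplitude 1
    a = 1.0
    if activates(a):
        upper = a
        lower = None
        while a > lo:
            a /= 10.0
            if not activates(a):
                lower = a
                break
            upper = a
        if lower is None:
            raise RuntimeError(f"fiber activates at the minimum bound {lo}")
    else:
        lower = a
        upper = None
        while a < hi:
            a *= 10.0
            if activates(a):
                upper = a
                break
            lower = a
        if upper is None:
            raise RuntimeError(f"no activation up to the maximum bound {hi}")
    while (upper - lower) / lower > rel_tol:
        mid = math.sqrt(lower * upper)
        if activates(mid):
            upper = mid
        else:
            lower = mid
    return upper


# ---------------------------------------------------------------------------
# Strength–duration protocol
# ---------------------------------------------------------------------------


def fit_sd(widths_s, thresholds, units: str = "V/m") -> SDCurve:
    """Least-squares fit of the hyperbolic S-D law.

    I = b(1 + C/w) is linear in (b, b·C); the residuals are weighted by
    1/I (relative error), since threshold scatter is multiplicative and
    thresholds span more than a decade across the width range.  C is
    recovered as the coefficient ratio.  The fit is exact on noise-free
    hyperbolic data.
    """
    w = np.asarray(widths_s, dtype=float)
    th = np.asarray(thresholds, dtype=float)
    if w.shape != th.shape or w.size < 2:
        raise ValueError("need matching widths/thresholds, at least 2 points")
    if np.any(th <= 0) or np.any(w <= 0):
        raise ValueError("widths and thresholds must be positive")
    A = np.column_stack([np.ones_like(w), 1.0 / w]) / th[:, None]
    coef, *_ = np.linalg.lstsq(A, np.ones_like(th), rcond=None)
    b, bc = coef
    if b <= 0 or bc <= 0:
        raise ValueError("S-D fit produced non-positive rheobase or chronaxie")
    resid = float(np.sqrt(np.mean((A @ coef - 1.0) ** 2)))
    return SDCurve(widths_s=w, thresholds=th, rheobase=float(b),
                   chronaxie_s=float(bc / b), residual=resid, units=units)


def sd_protocol(path: FiberPath, params: AxonParams,
                widths_s=DEFAULT_WIDTHS_S,
                interval_s: float = DEFAULT_INTERVAL_S,
                rel_tol: float = 0.01, **search_kw) -> SDCurve:
    """Measure the S-D curve with bipolar pulse pairs and fit (b, C)."""
    th = [find_threshold(path, params,
                         StimulusWaveform.bipolar_pulse(w, interval_s),
                         rel_tol=rel_tol, **search_kw)
          for w in widths_s]
    units = "V/m" if "V/m" in str(path.meta.get("ve_basis", "")) else "mT"
    return fit_sd(widths_s, th, units=units)


def convert_rheobase(conv: RheobaseConversion) -> RheobaseConversion:
    """Complete the external↔internal rheobase conversion.

    E_th / E_sim = (dB/dt)_th / (dB/dt)_sim; exactly one field must be
    missing and is computed from the other three.
    """
    vals = {k: getattr(conv, k) for k in
            ("dBdt_th", "dBdt_sim", "E_sim", "E_th")}
    missing = [k for k, v in vals.items() if v is None]
    if len(missing) != 1:
        raise ValueError(
            f"exactly one field must be missing, got {len(missing)}")
    for k, v in vals.items():
        if v is not None and v <= 0:
            raise ValueError(f"{k} must be positive")
    k = missing[0]
    if k == "E_th":
        vals[k] = vals["E_sim"] * vals["dBdt_th"] / vals["dBdt_sim"]
    elif k == "E_sim":
        vals[k] = vals["E_th"] * vals["dBdt_sim"] / vals["dBdt_th"]
    elif k == "dBdt_th":
        vals[k] = vals["dBdt_sim"] * vals["E_th"] / vals["E_sim"]
    else:
        vals[k] = vals["dBdt_th"] * vals["E_sim"] / vals["E_th"]
    return RheobaseConversion(**vals)


def scale_threshold_inverse_diameter(threshold: float, diameter_from_um: float,
                                     diameter_to_um: float) -> float:
    """Rescale a threshold between fiber diameters (threshold ∝ 1/diameter)."""
    if diameter_from_um <= 0 or diameter_to_um <= 0:
        raise ValueError("diameters must be positive")
    return threshold * diameter_from_um / diameter_to_um


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    params: AxonParams
    curve: SDCurve
    error: float            # max relative deviation of (b, C) from targets
    converged: bool
    history: list = dc_field(default_factory=list)


def calibrate_params(path: FiberPath, base: AxonParams, target_b: float,
                     target_c_s: float, *,
                     grid_c=(4.0, 5.0, 6.0, 7.0, 8.0, 8.5),
                     grid_gna=(3.0, 4.5, 6.0, 8.0, 10.0),
                     grid_gl=(0.25,),
                     widths_s=DEFAULT_WIDTHS_S, rel_tol: float = 0.01,
                     tol: float = 0.10, max_rounds: int = 3,
                     **search_kw) -> CalibrationResult:
    """Fit the response multipliers (C, G_Na, G_l) to S-D targets.

    Coordinate descent over the multiplier grids, minimizing the joint error
    max(|b−b*|/b*, |C−C*|/C*) of the fitted rheobase and chronaxie under the
    uniform-field S-D protocol.  Stops when the error falls below ``tol``
    (the experimental fit-quality bound) or the grids are exhausted, in
    which case the best point is returned with ``converged=False``.
    """
    if target_b <= 0 or target_c_s <= 0:
        raise ValueError("targets must be positive")
    grids = {"mult_c": tuple(grid_c), "mult_gna": tuple(grid_gna),
             "mult_gl": tuple(grid_gl)}
    current = {"mult_c": base.mult_c, "mult_gna": base.mult_gna,
               "mult_gl": base.mult_gl}
    for k, g in grids.items():
        if current[k] not in g:
            current[k] = g[len(g) // 2]
    cache: dict[tuple, tuple[SDCurve, float]] = {}
    history = []

    def objective(m):
        key = (m["mult_c"], m["mult_gna"], m["mult_gl"])
        if key not in cache:
            p = base.with_multipliers(*key)
            curve = sd_protocol(path, p, widths_s=widths_s, rel_tol=rel_tol,
                                **search_kw)
            err = max(abs(curve.rheobase - target_b) / target_b,
                      abs(curve.chronaxie_s - target_c_s) / target_c_s)
            cache[key] = (curve, err)
            history.append((key, curve.rheobase, curve.chronaxie_s, err))
        return cache[key][1]

    best_err = objective(current)
    for _ in range(max_rounds):
        improved = False
        for name in ("mult_c", "mult_gna", "mult_gl"):
            if best_err <= tol:
                break
            for cand in grids[name]:
                trial = dict(current)
                trial[name] = cand
                err = objective(trial)
                if err < best_err:
                    best_err, current, improved = err, trial, True
        if best_err <= tol or not improved:
            break
    key = (current["mult_c"], current["mult_gna"], current["mult_gl"])
    curve, err = cache[key]
    return CalibrationResult(params=base.with_multipliers(*key), curve=curve,
                             error=err, converged=err <= tol, history=history)


# ---------------------------------------------------------------------------
# Fiber populations
# ---------------------------------------------------------------------------


@dataclass
class PopulationResult:
    thresholds_mt: np.ndarray          # per-fiber external B threshold, mT
    group_sizes: np.ndarray
    group_medians_mt: np.ndarray
    group_iqr_mt: np.ndarray
    fibers: list


def population_thresholds(hotspots, field, params: AxonParams,
                          n_fibers: int, *, curved: bool = True,
                          waveform: StimulusWaveform | None = None,
                          diameter_um: float = 20.0, n_nodes: int = 21,
                          group_sizes=None, seed: int = 0,
                          rel_tol: float = 0.01,
                          **search_kw) -> PopulationResult:
    """External B-field thresholds for fibers seeded on field hotspots.

    Fibers are centered on the top-ranked hotspot positions, bent along the
    field (or straight along the local field direction when ``curved`` is
    False), and their activation thresholds are expressed as the external
    magnetic flux density (mT, peak) through the 1 mT quasi-potential basis.
    Group medians over random subsets of increasing size show how many
    fibers are needed for a stable median.
    """
    if waveform is None:
        waveform = StimulusWaveform.sinusoid(field.exposure.frequency_hz)
    entries = hotspots.entries[:n_fibers]
    if len(entries) < n_fibers:
        raise ValueError(f"only {len(entries)} hotspots available")
    ths, fibers = [], []
    for e in entries:
        center = e.world_mm
        try:
            if curved:
                f = curved_fiber(center, field, diameter_um=diameter_um,
                                 n_nodes=n_nodes)
            else:
                ev = _local_field_direction(field, center)
                f = straight_along(center, ev, diameter_um=diameter_um,
                                   n_nodes=n_nodes)
            sample_quasipotential(f, field)
            th = find_threshold(f, params, waveform, rel_tol=rel_tol,
                                **search_kw)
        except (RuntimeError, ValueError):
            # fiber did not fit the field grid or did not activate in
            # bounds; keep the slot so group statistics stay aligned
            f, th = None, np.nan
        ths.append(th)
        fibers.append(f)
    ths = np.asarray(ths)
    if group_sizes is None:
        group_sizes = [s for s in range(10, n_fibers + 1, 10)] or [n_fibers]
    rng = np.random.default_rng(seed)
    medians, iqrs = [], []
    for s in group_sizes:
        s = min(s, n_fibers)
        sub = ths[rng.choice(n_fibers, size=s, replace=False)] \
            if s < n_fibers else ths
        medians.append(np.nanmedian(sub))
        iqrs.append(np.subtract(*np.nanpercentile(sub, [75, 25])))
    return PopulationResult(thresholds_mt=ths,
                            group_sizes=np.asarray(group_sizes),
                            group_medians_mt=np.asarray(medians),
                            group_iqr_mt=np.asarray(iqrs), fibers=fibers)


def _local_field_direction(field, center_mm):
    from .fibers import _field_interpolator
    e = _field_interpolator(field)(np.asarray(center_mm, float))[0]
    n = np.linalg.norm(e)
    if n == 0:
        raise ValueError("induced field vanishes at fiber center")
    return e / n


def straight_along(center_mm, direction, *, diameter_um: float = 20.0,
                   n_nodes: int = 21) -> FiberPath:
    """Straight fiber through a point along an arbitrary 3-D direction."""
    from .fibers import _template_arclengths
    u = np.asarray(direction, float)
    u /= np.linalg.norm(u)
    s, is_node = _template_arclengths(n_nodes, diameter_um)
    pts = np.asarray(center_mm, float) + (s - s[-1] / 2.0)[:, None] * u
    return FiberPath(points=pts, is_node=is_node, diameter_um=diameter_um,
                     meta={"geometry": "straight", "direction": u.tolist()})
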