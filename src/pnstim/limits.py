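"""Exposure-limit curves and margin factors.

Protection limits are piecewise power-law curves of frequency — internal
electric field (basic restrictions / dosimetric reference limits) or
external magnetic flux density (reference levels / exposure reference
levels).  The formulas ship as YAML fixtures (data, not code) so that
standards revisions can be swapped and audited; each fixture records its
provenance and whether its values are peak or rms.

A margin report divides computed thresholds by the limit at each frequency;
a margin factor > 1 means the threshold exceeds the limit, i.e. the limit
is conservative by that factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["LimitSegment", "LimitCurve", "MarginReport", "load_limit",
           "packaged_limits", "eval_limit", "margin_report"]

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class LimitSegment:
    """One piece of a limit curve: value = a · f^p + c on [f_low, f_high)."""

    f_low: float
    f_high: float
    a: float = 0.0
    p: float = 0.0
    c: float = 0.0

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        return self.a * f ** self.p + self.c


@dataclass
class LimitCurve:
    """Piecewise exposure-limit curve with provenance metadata."""

    name: str
    quantity: str            # 'internal_E' | 'external_B'
    unit: str                # 'V/m' | 'T'
    convention: str          # 'rms' | 'peak'
    segments: list[LimitSegment]
    citation: str = ""

    def __post_init__(self):
        if self.quantity not in ("internal_E", "external_B"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.convention not in ("rms", "peak"):
            raise ValueError("convention must be 'rms' or 'peak'")
        segs = sorted(self.segments, key=lambda s: s.f_low)
        for a, b in zip(segs[:-1], segs[1:]):
            if a.f_high > b.f_low + 1e-9:
                raise ValueError(f"overlapping segments in {self.name}")
        self.segments = segs

    @property
    def f_range(self) -> tuple[float, float]:
        return self.segments[0].f_low, self.segments[-1].f_high

    def value_peak(self, f):
        """Limit converted to peak convention (sinusoidal, ×√2 from rms)."""
        v = eval_limit(self, f)
        return v * SQRT2 if self.convention == "rms" else v


def eval_limit(curve: LimitCurve, f) -> float | np.ndarray:
    """Evaluate the limit at frequency(ies) ``f`` in the curve's own
    convention and units; errors outside the covered band."""
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    out = np.full(f_arr.shape, np.nan)
    for seg in curve.segments:
        m = (f_arr >= seg.f_low) & (f_arr < seg.f_high)
        # closed at the top end of the final segment
        if seg is curve.segments[-1]:
            m |= f_arr == seg.f_high
        out[m] = seg(f_arr[m])
    if np.any(np.isnan(out)):
        bad = f_arr[np.isnan(out)]
        raise ValueError(
            f"frequency {bad[0]:g} Hz outside '{curve.name}' coverage "
            f"{curve.f_range}")
    return float(out[0]) if np.isscalar(f) else out.reshape(np.shape(f))


def load_limit(path) -> LimitCurve:
    """Load a limit-curve YAML fixture."""
    data = yaml.safe_load(Path(path).read_text())
    segs = [LimitSegment(**{k: float(v) for k, v in s.items()})
            for s in data["segments"]]
    return LimitCurve(name=data["name"], quantity=data["quantity"],
                      unit=data["unit"], convention=data["convention"],
                      segments=segs, citation=data.get("citation", ""))


def packaged_limits() -> dict[str, LimitCurve]:
    """The limit fixtures shipped with the package, keyed by name."""
    out = {}
    root = resources.files("pnstim.data").joinpath("limits")
    for entry in root.iterdir():
        if entry.name.endswith(".yaml"):
            with resources.as_file(entry) as p:
                c = load_limit(p)
            out[c.name] = c
    return out


@dataclass
class MarginReport:
    """Threshold-to-limit ratios over a frequency band."""

    curve_name: str
    quantity: str
    frequencies_hz: np.ndarray
    thresholds: np.ndarray        # peak convention, curve units
    limits: np.ndarray            # converted to peak convention
    ratios: np.ndarray
    min_ratio: float
    response_class: str = ""

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"frequency_hz": self.frequencies_hz,
                             "threshold": self.thresholds,
                             "limit": self.limits, "ratio": self.ratios})


def margin_report(thresholds: dict[float, float], curve: LimitCurve,
                  response_class: str = "",
                  thresholds_convention: str = "peak") -> MarginReport:
    """Margin factors of computed thresholds over a limit curve.

    ``thresholds`` maps frequency (Hz) to the computed threshold in the
    curve's units.  Thresholds and limits are compared in peak convention
    (rms limits are multiplied by √2); ratios are pointwise and the band
    minimum is reported.
    """
    if thresholds_convention not in ("peak", "rms"):
        raise ValueError("thresholds_convention must be 'peak' or 'rms'")
    freqs = np.array(sorted(thresholds))
    th = np.array([thresholds[f] for f in freqs], dtype=float)
    if thresholds_convention == "rms":
        th = th * SQRT2
    if np.any(th <= 0):
        raise ValueError("thresholds must be positive")
    lim = np.asarray(curve.value_peak(freqs), dtype=float)
    ratios = th / lim
    return MarginReport(curve_name=curve.name, quantity=curve.quantity,
                        frequencies_hz=freqs, thresholds=th, limits=lim,
                        ratios=ratios, min_ratio=float(ratios.min()),
                        response_class=response_class)
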