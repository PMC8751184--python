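"""Frequency-dependent tissue conductivity from the 4-Cole-Cole model.

The complex relative permittivity of a tissue is modeled as four Cole-Cole
dispersion terms plus a static ionic conductivity:

    ε̂(ω) = ε_∞ + Σₙ Δεₙ / (1 + (jωτₙ)^(1−αₙ)) + σᵢ / (jωε₀)

The effective conductivity used by the quasistatic field solver is the real
part of jωε₀ε̂(ω); displacement currents (the permittivity part) are
neglected, as conduction currents dominate by an order of magnitude in the
300 Hz – 1 MHz band.

Dispersion constants for the phantom tissues ship as a packaged CSV
transcribed from the standard literature parameterization; the table is
config-replaceable via :func:`load_cole_cole_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ColeColeParams", "ConductivityMap", "cole_cole_sigma",
           "assign_conductivity", "load_cole_cole_table"]

EPS0 = 8.8541878128e-12  # F/m


@dataclass(frozen=True)
class ColeColeParams:
    """4-Cole-Cole dispersion constants of one tissue."""

    eps_inf: float
    sigma_i: float                       # S/m, static ionic conductivity
    delta_eps: tuple[float, float, float, float]
    tau_s: tuple[float, float, float, float]      # relaxation times, s
    alpha: tuple[float, float, float, float]      # broadening, in [0, 1)

    def __post_init__(self):
        if self.sigma_i < 0:
            raise ValueError("sigma_i must be non-negative")
        if any(t <= 0 for t in self.tau_s):
            raise ValueError("relaxation times must be positive")
        if any(not (0 <= a < 1) for a in self.alpha):
            raise ValueError("alpha must lie in [0, 1)")


@dataclass
class ConductivityMap:
    """Per-voxel conductivity (S/m) at one frequency; air voxels are 0."""

    sigma: np.ndarray
    frequency_hz: float
    grid: object = None   # TissueGrid the map was built from

    def __post_init__(self):
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")


def cole_cole_sigma(params: ColeColeParams, f_hz) -> float | np.ndarray:
    """Effective conductivity σ(f) = Re[jωε₀ε̂(ω)] in S/m.

    Only the conduction part is returned; the imaginary (permittivity) part
    is discarded.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2 * np.pi * f
    eps = np.full(f.shape, params.eps_inf, dtype=complex) \
        if f.shape else complex(params.eps_inf)
    for de, tau, al in zip(params.delta_eps, params.tau_s, params.alpha):
        eps = eps + de / (1.0 + (1j * w * tau) ** (1.0 - al))
    eps = eps + params.sigma_i / (1j * w * EPS0)
    sigma = np.real(1j * w * EPS0 * eps)
    return float(sigma) if np.isscalar(f_hz) else sigma


def load_cole_cole_table(path=None) -> dict[str, ColeColeParams]:
    """Load a tissue → Cole-Cole parameter table.

    The CSV has columns ``tissue, eps_inf, sigma_i, delta_eps_1..4,
    tau_1..4, alpha_1..4`` (taus in seconds).  Without a path, the packaged
    default table (skin, fat, muscle, bone) is used.
    """
    if path is None:
        src = resources.files("pnstim.data").joinpath("cole_cole.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["tissue"])] = ColeColeParams(
            eps_inf=float(row["eps_inf"]), sigma_i=float(row["sigma_i"]),
            delta_eps=tuple(float(row[f"delta_eps_{n}"]) for n in range(1, 5)),
            tau_s=tuple(float(row[f"tau_{n}"]) for n in range(1, 5)),
            alpha=tuple(float(row[f"alpha_{n}"]) for n in range(1, 5)),
        )
    return out


def assign_conductivity(grid, table: dict[str, ColeColeParams],
                        f_hz: float) -> ConductivityMap:
    """Per-voxel conductivity map at ``f_hz``; air is exactly 0.

    Every non-air tissue present in the grid must have an entry in
    ``table`` (by tissue name).
    """
    sigma = np.zeros(grid.shape, dtype=float)
    for lab in np.unique(grid.labels):
        if lab == 0:
            continue
        name = grid.tissue_names[int(lab)]
        if name not in table:
            raise KeyError(
                f"tissue '{name}' (label {int(lab)}) has no dielectric "
                f"parameters")
        sigma[grid.labels == lab] = cole_cole_sigma(table[name], f_hz)
    return ConductivityMap(sigma=sigma, frequency_hz=float(f_hz), grid=grid)
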