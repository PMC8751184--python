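"""Compartmental cable model of a myelinated axon with CRRSS nodal dynamics.

The axon is a chain of alternating node-of-Ranvier and internode compartments
(SENN-family morphology).  Nodes carry the Chiu–Ritchie–Rogart–Stagg–Sweeney
(CRRSS) membrane: a voltage-gated sodium current with m²h kinetics plus a
linear leak; internodes are passive (myelin capacitance and conductance).
Membrane potential is expressed relative to rest, so V = 0 everywhere is the
resting state.

The extracellular drive enters through the quasi-potential sampled along the
fiber (see :mod:`pnstim.fibers`): the axial-difference stencil applied to the
extracellular potential is the source term ("activating function" form).

Integration is Crank–Nicolson on the linear cable with exponential-Euler
gating, which is unconditionally stable and second-order in the membrane
voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "AxonParams",
    "MembraneTrace",
    "simulate",
    "detect_activation",
    "rate_constants",
    "gating_steady_state",
]

# ---------------------------------------------------------------------------
# CRRSS gating kinetics
# ---------------------------------------------------------------------------
# Rate functions for the sodium activation (m) and inactivation (h) gates of
# mammalian (rabbit) node of Ranvier, expressed at 37 °C.  v is the membrane
# depolarization from rest in mV; rates are in 1/ms.


def _alpha_m(v: np.ndarray) -> np.ndarray:
    return (97.0 + 0.363 * v) / (1.0 + np.exp((31.0 - v) / 5.3))


def _beta_m(v: np.ndarray) -> np.ndarray:
    return _alpha_m(v) / np.exp((v - 23.8) / 4.17)


def _beta_h(v: np.ndarray) -> np.ndarray:
    return 15.6 / (1.0 + np.exp((24.0 - v) / 10.0))


def _alpha_h(v: np.ndarray) -> np.ndarray:
    return _beta_h(v) / np.exp((v - 5.5) / 5.0)


def rate_constants(v_mv: np.ndarray, temperature_c: float = 37.0,
                   q10: float = 3.0) -> tuple[np.ndarray, ...]:
    """CRRSS gating rates (1/s) at depolarization ``v_mv`` (mV from rest).

    The published rates are referenced to 37 °C; a Q10 factor rescales them
    for other temperatures.
    """
    v = np.clip(np.asarray(v_mv, dtype=float), -200.0, 300.0)
    k = q10 ** ((temperature_c - 37.0) / 10.0) * 1e3  # 1/ms -> 1/s, with Q10
    return (_alpha_m(v) * k, _beta_m(v) * k, _alpha_h(v) * k, _beta_h(v) * k)


def gating_steady_state(v_mv: float = 0.0, temperature_c: float = 37.0,
                        q10: float = 3.0) -> tuple[float, float]:
    """Steady-state (m∞, h∞) at a holding depolarization (default rest)."""
    am, bm, ah, bh = rate_constants(np.asarray(v_mv), temperature_c, q10)
    return float(am / (am + bm)), float(ah / (ah + bh))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: CRRSS per-area membrane constants (node of Ranvier)
G_NA_PER_AREA = 1445e1      # S/m^2  (1445 mS/cm^2)
G_L_PER_AREA = 128e1        # S/m^2  (128 mS/cm^2)
C_NODE_PER_AREA = 2.5e-2    # F/m^2  (2.5 uF/cm^2)
AXOPLASM_RESISTIVITY = 1.10  # Ohm*m (110 Ohm*cm, SENN-family convention)

#: SENN-family morphology ratios
AXON_DIAMETER_RATIO = 0.7   # axon (inner) diameter / fiber (outer) diameter
INTERNODE_LENGTH_RATIO = 100.0  # internode length / fiber diameter
NODE_LENGTH_M = 1.5e-6      # nodal gap length, fixed across diameters

#: Lumped internode (myelin) membrane elements at the 20 um reference
#: diameter.  With a constant g-ratio the lamella count grows with
#: diameter, so per-internode myelin capacitance and conductance scale
#: linearly with D (area ∝ D², per-area values ∝ 1/D).  Together with the
#: fixed nodal gap this makes activation thresholds scale as 1/D.
C_MYELIN_20UM = 2.89e-11    # F (≈0.023 uF/cm² over a 20 um × 2 mm internode)
G_MYELIN_20UM = 26.8e-9     # S


@dataclass(frozen=True)
class AxonParams:
    """Lumped electrical parameters of one node / internode unit.

    All elements are per-compartment lumped values in SI units; the response
    multipliers (``mult_c``, ``mult_gna``, ``mult_gl``) rescale nodal
    capacitance, sodium conductance and leak conductance and are the fitting
    knobs used to match experimental strength–duration data.
    """

    diameter_um: float
    c_node: float            # F
    c_internode: float       # F
    g_na: float              # S, maximal sodium conductance per node
    g_leak: float            # S, nodal leak
    g_myelin: float          # S, internode membrane conductance
    r_axial_node: float      # Ohm, axial resistance of a node compartment
    r_axial_internode: float  # Ohm, axial resistance of an internode
    e_na_mv: float = 115.0
    e_leak_mv: float = -0.01
    temperature_c: float = 37.0
    q10: float = 3.0
    mult_c: float = 1.0
    mult_gna: float = 1.0
    mult_gl: float = 1.0

    def __post_init__(self):
        for name in ("c_node", "c_internode", "g_na", "g_leak", "g_myelin",
                     "r_axial_node", "r_axial_internode"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (after multipliers)")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_geometry(cls, diameter_um: float = 20.0, *,
                      mult_c: float = 1.0, mult_gna: float = 1.0,
                      mult_gl: float = 1.0, temperature_c: float = 37.0,
                      e_leak_mv: float | str = "auto") -> "AxonParams":
        """Derive lumped elements from per-area CRRSS constants and geometry.

        Axon diameter is 0.7× the fiber diameter, internode length 100× the
        fiber diameter, nodal gap 1.5 μm.  Nodal capacitance and conductances
        are per-area constants times the nodal membrane area; axial
        resistances follow from axoplasm resistivity and the axon cross
        section, so thresholds scale inversely with diameter.
        """
        d_fiber = diameter_um * 1e-6
        d_axon = AXON_DIAMETER_RATIO * d_fiber
        l_internode = INTERNODE_LENGTH_RATIO * d_fiber
        a_node = np.pi * d_axon * NODE_LENGTH_M          # nodal membrane area
        a_axial = np.pi * (d_axon / 2.0) ** 2

        g_na = G_NA_PER_AREA * a_node * mult_gna
        g_leak = G_L_PER_AREA * a_node * mult_gl
        c_node = C_NODE_PER_AREA * a_node * mult_c
        c_internode = C_MYELIN_20UM * diameter_um / 20.0
        g_myelin = G_MYELIN_20UM * diameter_um / 20.0
        r_node = AXOPLASM_RESISTIVITY * NODE_LENGTH_M / a_axial
        r_internode = AXOPLASM_RESISTIVITY * l_internode / a_axial

        el = cls._balanced_e_leak(g_na, g_leak, temperature_c) \
            if e_leak_mv == "auto" else float(e_leak_mv)
        return cls(diameter_um=diameter_um, c_node=c_node,
                   c_internode=c_internode, g_na=g_na, g_leak=g_leak,
                   g_myelin=g_myelin, r_axial_node=r_node,
                   r_axial_internode=r_internode, e_leak_mv=el,
                   temperature_c=temperature_c, mult_c=mult_c,
                   mult_gna=mult_gna, mult_gl=mult_gl)

    @classmethod
    def from_table(cls, diameter_um: float = 20.0, *,
                   mult_c: float = 1.0, mult_gna: float = 1.0,
                   mult_gl: float = 1.0, temperature_c: float = 37.0,
                   e_leak_mv: float | str = "auto") -> "AxonParams":
        """Lumped elements as printed in the source parameter table.

        Interpretation: the kΩ-scale resistances are compartment axial
        resistances, the nF-scale capacitances per-compartment membrane
        capacitances, the nS myelin conductance the internode membrane leak,
        and the per-area sodium/leak conductances are multiplied by the nodal
        membrane area.  These magnitudes are mutually inconsistent with the
        per-area constants (see docs/methods.md); :meth:`from_geometry` is
        the default used everywhere else in the package.
        """
        d_axon = AXON_DIAMETER_RATIO * diameter_um * 1e-6
        a_node = np.pi * d_axon * NODE_LENGTH_M
        g_na = G_NA_PER_AREA * a_node * mult_gna
        g_leak = G_L_PER_AREA * a_node * mult_gl
        el = cls._balanced_e_leak(g_na, g_leak, temperature_c) \
            if e_leak_mv == "auto" else float(e_leak_mv)
        return cls(diameter_um=diameter_um,
                   c_node=30.2e-9 * mult_c, c_internode=28.8e-9,
                   g_na=g_na, g_leak=g_leak, g_myelin=26.8e-9,
                   r_axial_node=3.26e3, r_axial_internode=218e3,
                   e_leak_mv=el, temperature_c=temperature_c,
                   mult_c=mult_c, mult_gna=mult_gna, mult_gl=mult_gl)

    @classmethod
    def perceptual(cls, diameter_um: float = 20.0) -> "AxonParams":
        """Calibrated preset for the perception-threshold response class."""
        return cls.from_geometry(diameter_um, mult_c=6.0, mult_gna=8.0,
                                 mult_gl=0.25)

    @classmethod
    def uncomfortable(cls, diameter_um: float = 20.0) -> "AxonParams":
        """Calibrated preset for the uncomfortable-response class."""
        return cls.from_geometry(diameter_um, mult_c=8.5, mult_gna=4.5,
                                 mult_gl=0.25)

    def with_multipliers(self, mult_c: float, mult_gna: float,
                         mult_gl: float) -> "AxonParams":
        """Return a copy re-derived with different response multipliers."""
        base_c = self.c_node / self.mult_c
        base_gna = self.g_na / self.mult_gna
        base_gl = self.g_leak / self.mult_gl
        g_na = base_gna * mult_gna
        g_leak = base_gl * mult_gl
        el = self._balanced_e_leak(g_na, g_leak, self.temperature_c)
        return replace(self, c_node=base_c * mult_c, g_na=g_na,
                       g_leak=g_leak, e_leak_mv=el, mult_c=mult_c,
                       mult_gna=mult_gna, mult_gl=mult_gl)

    @staticmethod
    def _balanced_e_leak(g_na: float, g_leak: float,
                         temperature_c: float) -> float:
        # leak reversal that cancels the resting sodium window current, so
        # that V = 0 is an exact equilibrium of the nodal membrane
        m0, h0 = gating_steady_state(0.0, temperature_c)
        return -(g_na * m0 ** 2 * h0 / g_leak) * 115.0


@dataclass
class MembraneTrace:
    """Membrane-potential history of one simulation.

    ``v_mv`` is (n_times, n_compartments), relative to rest;
    ``node_index`` maps node order to compartment columns.
    """

    times: np.ndarray          # s, strictly increasing
    v_mv: np.ndarray           # (nt, M) depolarization in mV
    node_index: np.ndarray     # compartment indices that are nodes
    m: np.ndarray | None = None   # final gating states at nodes
    h: np.ndarray | None = None

    def node_potentials(self) -> np.ndarray:
        return self.v_mv[:, self.node_index]

    def to_hdf5(self, path) -> None:
        """Dump the trace (time × compartment) to an HDF5 file."""
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times_s", data=self.times)
            f.create_dataset("v_mv", data=self.v_mv)
            f.create_dataset("node_index", data=self.node_index)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _cable_elements(kinds: np.ndarray, p: AxonParams):
    """Per-compartment capacitance/linear-conductance and axial conductances."""
    is_node = kinds
    c = np.where(is_node, p.c_node, p.c_internode)
    g_lin = np.where(is_node, p.g_leak, p.g_myelin)
    r = np.where(is_node, p.r_axial_node, p.r_axial_internode)
    g_ax = 1.0 / (0.5 * (r[:-1] + r[1:]))   # between k and k+1
    return c, g_lin, g_ax


def _laplacian_apply(g_ax: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(A x)_k = sum_j g_kj (x_k - x_j) for the chain graph."""
    out = np.zeros_like(x)
    d = g_ax * (x[1:] - x[:-1])
    out[:-1] -= d
    out[1:] += d
    return out


def simulate(path, params: AxonParams, waveform: Callable[[np.ndarray], np.ndarray],
             dt: float, duration: float, amplitude: float = 1.0,
             record_every: int = 1) -> MembraneTrace:
    """Integrate the cable equation driven by the fiber's quasi-potential.

    Parameters
    ----------
    path
        :class:`~pnstim.fibers.FiberPath` with the per-compartment
        quasi-potential ``ve`` (V, unit-exposure basis).
    params
        Axon electrical parameters.
    waveform
        Callable mapping a time array (s) to the dimensionless stimulus
        waveform; the extracellular potential at time t is
        ``amplitude * ve * waveform(t)``.
    dt, duration
        Time step and total integration time (s).
    amplitude
        Scale factor on the unit-basis quasi-potential.
    record_every
        Keep every k-th sample in the returned trace.

    Returns
    -------
    MembraneTrace
    """
    ve = np.asarray(path.ve, dtype=float)
    if ve.ndim != 1 or ve.size != len(path.kinds):
        raise ValueError("path.ve must be per-compartment")
    is_node = path.is_node
    M = ve.size
    c, g_lin, g_ax = _cable_elements(is_node, params)
    node_idx = np.flatnonzero(is_node)

    nt = int(round(duration / dt))
    times = np.arange(nt + 1) * dt
    w = np.asarray(waveform(times), dtype=float)
    if w.shape != times.shape:
        raise ValueError("waveform must return one value per time sample")

    m0, h0 = gating_steady_state(0.0, params.temperature_c, params.q10)
    m = np.full(node_idx.size, m0)
    h = np.full(node_idx.size, h0)
    v = np.zeros(M)

    e_na = params.e_na_mv * 1e-3
    e_l = params.e_leak_mv * 1e-3
    g_na_max = params.g_na

    # banded matrix template: rows = (upper, diag, lower)
    ab = np.zeros((3, M))
    inv_dt = c / dt

    # precompute activating-function source basis: -A ve (current into each
    # compartment per unit waveform value per unit amplitude)
    src_basis = -_laplacian_apply(g_ax, ve) * amplitude

    # nodal sodium conductance at t=0
    g_na_now = g_na_max * m ** 2 * h

    n_rec = nt // record_every + 1
    v_rec = np.empty((n_rec, M))
    t_rec = np.empty(n_rec)
    v_rec[0] = 0.0
    t_rec[0] = 0.0
    rec_i = 1

    g_mem_now = g_lin.copy()
    g_mem_now[node_idx] += g_na_now
    e_src_now = np.zeros(M)
    e_src_now[node_idx] = g_na_now * e_na + params.g_leak * e_l

    for it in range(nt):
        v_node_mv = v[node_idx] * 1e3
        am, bm, ah, bh = rate_constants(v_node_mv, params.temperature_c,
                                        params.q10)
        # exponential Euler gating update
        tm = 1.0 / (am + bm)
        th = 1.0 / (ah + bh)
        m = am * tm + (m - am * tm) * np.exp(-dt / tm)
        h = ah * th + (h - ah * th) * np.exp(-dt / th)
        g_na_new = g_na_max * m ** 2 * h
        g_mem_new = g_lin.copy()
        g_mem_new[node_idx] += g_na_new
        e_src_new = np.zeros(M)
        e_src_new[node_idx] = g_na_new * e_na + params.g_leak * e_l

        s_old = src_basis * w[it] + e_src_now
        s_new = src_basis * w[it + 1] + e_src_new

        # Crank-Nicolson: (C/dt + (A+G)/2) v_new =
        #                 (C/dt - (A+G)/2) v_old + (s_old+s_new)/2
        rhs = (inv_dt - 0.5 * g_mem_now) * v \
            - 0.5 * _laplacian_apply(g_ax, v) + 0.5 * (s_old + s_new)

        half_g = 0.5 * g_mem_new
        ab[1, :] = inv_dt + half_g
        ab[1, :-1] += 0.5 * g_ax
        ab[1, 1:] += 0.5 * g_ax
        ab[0, 1:] = -0.5 * g_ax
        ab[2, :-1] = -0.5 * g_ax
        v = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"cable integration diverged at t={times[it + 1]:.3e}s; "
                f"reduce dt (currently {dt:.3e}s)")
        g_mem_now = g_mem_new
        e_src_now = e_src_new

        if (it + 1) % record_every == 0:
            v_rec[rec_i] = v
            t_rec[rec_i] = times[it + 1]
            rec_i += 1

    return MembraneTrace(times=t_rec[:rec_i], v_mv=v_rec[:rec_i] * 1e3,
                         node_index=node_idx, m=m, h=h)


def detect_activation(trace: MembraneTrace, level_mv: float = 80.0,
                      n_nodes: int = 4) -> bool:
    """Propagating-spike detection rule.

    True iff at least ``n_nodes`` adjacent nodes each depolarize beyond
    ``level_mv`` with strictly ordered first-crossing times along the run
    (monotone in either direction), i.e. a propagating action potential
    rather than a simultaneous artifact.
    """
    vn = trace.node_potentials()
    crossed = vn >= level_mv
    any_cross = crossed.any(axis=0)
    first = np.where(any_cross, crossed.argmax(axis=0), -1)
    n = vn.shape[1]
    for start in range(n - n_nodes + 1):
        run = first[start:start + n_nodes]
        if np.any(run < 0):
            continue
        t = trace.times[run]
        d = np.diff(t)
        if np.all(d > 0) or np.all(d < 0):
            return True
    return False
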