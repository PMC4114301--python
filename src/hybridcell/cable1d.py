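"""1D electrical model: Hodgkin-Huxley membrane dynamics on the
compartment tree with axial coupling and current-clamp stimulation.

The membrane current balance per cylindrical compartment is

    c_m dV/dt = -(n^4 g_K (V-E_K) + m^3 h g_Na (V-E_Na) + g_L (V-E_L)
                  + I_Ca) + I_axial + I_electrode

with the classical 1952 rate functions for the gates.  The rate functions
are written in the original convention (V = displacement from rest,
depolarization negative); the solver's state is the absolute membrane
potential in mV with rest at -65 mV and converts at the interface.

Time stepping is Crank-Nicolson with staggered gates (gates live at
half-steps, conductances entering a V-step are therefore midpoint values),
the practice that keeps the scheme second-order.  Axial coupling across
branch points sums the currents of all children into the shared node, so
the per-step system is a sparse tree matrix, solved directly.

The calcium current I_Ca enters as an external per-compartment current
supplied by the hybrid driver (computed from back-mapped [Ca] via the GHK
flux); standalone runs may instead carry well-mixed per-compartment
channel gates and concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from . import vgcc
from .constants import (MS_PER_CM2_TO_US_PER_UM2, UF_PER_CM2_TO_NF_PER_UM2,
                        axial_resistance_megaohm)
from .errors import ConfigError, FullBlockageError, SolverError
from .morphology import CompartmentModel

V_REST_CONVENTION = -65.0   # absolute potential at which the 1952 V is 0


@dataclass(frozen=True)
class MembraneParams:
    """Membrane densities and reversal potentials (classical squid set;
    the units are the conventional ones, converted internally)."""

    c_m: float = 1.0          # uF/cm^2
    g_na: float = 120.0       # mS/cm^2
    g_k: float = 36.0         # mS/cm^2
    g_l: float = 0.3          # mS/cm^2
    e_na: float = 50.0        # mV (absolute)
    e_k: float = -77.0        # mV
    e_l: float = -54.4        # mV
    r_i: float = 100.0        # Ohm*cm intracellular resistivity
    temperature: float = 300.0  # K

    def __post_init__(self):
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ConfigError("conductances must be non-negative")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


@dataclass
class StimProtocol:
    """Square current-clamp pulse (reference protocol: 0.1 nA for 10 ms)."""

    compartment: int | None = None   # None -> soma midpoint / middle
    amplitude: float = 0.1           # nA
    onset: float = 0.0               # ms
    duration: float = 10.0           # ms

    def __post_init__(self):
        if self.duration < 0:
            raise ConfigError("stimulus duration must be >= 0")

    def current(self, t0: float, t1: float) -> float:
        """Average electrode current over [t0, t1] (nA); exact for pulses
        aligned with step boundaries, area-true otherwise."""
        lo, hi = self.onset, self.onset + self.duration
        overlap = max(0.0, min(t1, hi) - max(t0, lo))
        return self.amplitude * overlap / (t1 - t0)


def hh_rates(V):
    """The six 1952 rate functions [1/ms] at displacement-convention V.

    Removable singularities (alpha_n at V = -10, alpha_m at V = -25) are
    evaluated by their series limits.
    """
    V = np.asarray(V, float)

    def ratefn(num_scale, shift):
        x = (V + shift) / 10.0
        small = np.abs(x) < 1.0e-7
        xs = np.where(small, 1.0, x)
        val = num_scale * 10.0 * np.where(small, 1.0 - x / 2.0,
                                          x / np.expm1(xs))
        return val

    alpha_n = ratefn(0.01, 10.0)
    beta_n = 0.125 * np.exp(V / 80.0)
    alpha_m = ratefn(0.1, 25.0)
    beta_m = 4.0 * np.exp(V / 18.0)
    alpha_h = 0.07 * np.exp(V / 20.0)
    beta_h = 1.0 / (np.exp((V + 30.0) / 10.0) + 1.0)
    return {"alpha_n": alpha_n, "beta_n": beta_n,
            "alpha_m": alpha_m, "beta_m": beta_m,
            "alpha_h": alpha_h, "beta_h": beta_h}


def gate_equilibrium(alpha, beta, tau0: float = 0.0):
    """x_inf = a/(a+b), tau = 1/(a+b) + tau0 (shared with the VGCC gates)."""
    return vgcc.gate_equilibrium(alpha, beta, tau0)


def hh_equilibrium_abs(v_abs):
    """Resting gate values n_inf, m_inf, h_inf at absolute potential."""
    r = hh_rates(v_to_hh(v_abs))
    n, _ = gate_equilibrium(r["alpha_n"], r["beta_n"])
    m, _ = gate_equilibrium(r["alpha_m"], r["beta_m"])
    h, _ = gate_equilibrium(r["alpha_h"], r["beta_h"])
    return n, m, h


def v_to_hh(v_abs):
    """Absolute mV -> original-convention displacement."""
    return -(np.asarray(v_abs, float) - V_REST_CONVENTION)


def axial_resistance(length_um: float, diameter_um: float,
                     r_i_ohm_cm: float) -> float:
    """R_a = R_i 4 l / (pi d^2) in MOhm (cylinder axial resistance)."""
    if min(length_um, diameter_um, r_i_ohm_cm) <= 0:
        raise ConfigError("axial resistance needs positive l, d, R_i")
    return axial_resistance_megaohm(length_um, diameter_um, r_i_ohm_cm)


@dataclass
class ObstacleSpec:
    """Cylindrical intracellular obstacle on a neurite.

    ``arc_position``: arc length along the morphology edge [um] of the
    obstacle center; ``length``: axial extent [um]; ``hindrance``: the
    circumference (= radius) ratio H in [0, 1]; ``edge``: morphology edge
    index the obstacle sits on.
    """

    arc_position: float
    length: float = 0.14
    hindrance: float = 0.5
    edge: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hindrance <= 1.0:
            raise ConfigError("hindrance must lie in [0, 1]")
        if self.length <= 0:
            raise ConfigError("obstacle length must be positive")


def apply_obstacle_correction(model: CompartmentModel,
                              obstacles: list[ObstacleSpec]
                              ) -> CompartmentModel:
    """Shrink the effective electrical diameter of occupied compartments.

    Every compartment whose axial span overlaps an obstacle gets
    d_new = d_old - d_obstacle with d_obstacle = H * d_old (the hindrance
    is a circumference, hence radius, ratio).  H = 1 would give d_new = 0,
    an infinite axial resistance, and is refused.
    """
    comps = [replace(c) for c in model.compartments]
    for obs in obstacles:
        lo = obs.arc_position - obs.length / 2.0
        hi = obs.arc_position + obs.length / 2.0
        hit = False
        for c in comps:
            if c.branch_edge != obs.edge:
                continue
            c_lo, c_hi = c.arc_start, c.arc_start + c.length
            if c_hi <= lo or c_lo >= hi:
                continue
            hit = True
            d_obstacle = obs.hindrance * c.diameter
            if d_obstacle >= c.d_eff:
                raise FullBlockageError(
                    f"obstacle with H={obs.hindrance} blocks compartment "
                    f"{c.index} completely (d_new would be "
                    f"{c.d_eff - d_obstacle:.3g} um)")
            c.d_eff = c.d_eff - d_obstacle
        if not hit:
            continue
    return CompartmentModel(comps, model.graph, model.soma_index)


@dataclass
class CableState:
    """Cable solver state: V absolute [mV], gates (staggered at t+dt/2),
    per-compartment intracellular calcium [uM] from back-mapping."""

    V: np.ndarray
    n: np.ndarray
    m: np.ndarray
    h: np.ndarray
    ca: np.ndarray
    t: float = 0.0


class CableModel:
    """Assembled multicompartment cable ready for time stepping."""

    def __init__(self, model: CompartmentModel,
                 params: MembraneParams = MembraneParams(),
                 channel: vgcc.BGParams | None = None,
                 ca_o_mM: float = 1.6):
        self.model = model
        self.params = params
        self.channel = channel
        self.ca_o_mM = ca_o_mM
        n = len(model)
        area = model.lateral_areas                     # um^2
        self.area = area
        self.capacitance = params.c_m * UF_PER_CM2_TO_NF_PER_UM2 * area  # nF
        to_us = MS_PER_CM2_TO_US_PER_UM2 * area
        self.g_na_max = params.g_na * to_us
        self.g_k_max = params.g_k * to_us
        self.g_l = params.g_l * to_us
        self.laplacian = self._axial_laplacian()       # uS, tree-coupled
        self.v_rest = self._resting_potential()
        # per-compartment channel-density scale (space-dependent placement)
        self.density_scale: np.ndarray | None = None

    # -- assembly ---------------------------------------------------------

    def _axial_laplacian(self) -> sp.csr_matrix:
        model, params = self.model, self.params
        n = len(model)
        rows, cols, vals = [], [], []
        for c in model.compartments:
            p = c.parent_index
            if p < 0:
                continue
            pc = model.compartments[p]
            r = (axial_resistance(c.length / 2, c.d_eff, params.r_i)
                 + axial_resistance(pc.length / 2, pc.d_eff, params.r_i))
            g = 1.0 / r    # uS
            rows += [c.index, p, c.index, p]
            cols += [c.index, p, p, c.index]
            vals += [g, g, -g, -g]
        return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)),
                                           shape=(n, n)))

    def _resting_potential(self) -> float:
        p = self.params

        def balance(v):
            n, m, h = hh_equilibrium_abs(v)
            return (p.g_k * n ** 4 * (v - p.e_k)
                    + p.g_na * m ** 3 * h * (v - p.e_na)
                    + p.g_l * (v - p.e_l))

        return brentq(balance, -90.0, -40.0, xtol=1e-10)

    # -- state ------------------------------------------------------------

    def initial_state(self, ca0_uM: float = 0.1) -> CableState:
        n = len(self.model)
        v = np.full(n, self.v_rest)
        ninf, minf, hinf = hh_equilibrium_abs(self.v_rest)
        state = CableState(V=v,
                           n=np.full(n, ninf), m=np.full(n, minf),
                           h=np.full(n, hinf), ca=np.full(n, ca0_uM), t=0.0)
        if self.channel is not None:
            cs = vgcc.ChannelState.at_equilibrium(v, self.channel)
            state.kl = cs
        return state

    # -- stepping ---------------------------------------------------------

    def _advance_gates(self, state: CableState, V_abs, dt: float):
        """Exponential-integrator gate update over dt at potential V_abs."""
        r = hh_rates(v_to_hh(V_abs))
        for name in ("n", "m", "h"):
            a, b = r[f"alpha_{name}"], r[f"beta_{name}"]
            x_inf, tau = gate_equilibrium(a, b)
            x = getattr(state, name)
            setattr(state, name,
                    np.clip(x_inf + (x - x_inf) * np.exp(-dt / tau), 0, 1))
        if self.channel is not None and hasattr(state, "kl"):
            state.kl = vgcc.gate_step_euler(state.kl, V_abs, dt, self.channel)

    def calcium_current(self, state: CableState) -> np.ndarray:
        """Per-compartment I_Ca [nA] from the well-mixed GHK model (used
        standalone; the hybrid driver passes its own I_Ca instead)."""
        if self.channel is None or self.channel.density == 0:
            return np.zeros(len(self.model))
        cs = state.kl
        i_pA_chan = vgcc.ghk_flux(state.V, state.ca, self.ca_o_mM,
                                  self.channel.p_ca,
                                  self.channel.temperature,
                                  self.channel.z_ion)
        dens = self.channel.density
        if self.density_scale is not None:
            dens = dens * self.density_scale
        return dens * cs.open_fraction(self.channel) * i_pA_chan \
            * self.area * 1.0e-3   # pA -> nA

    def step(self, state: CableState, stim: StimProtocol | None,
             dt: float, i_ca_nA: np.ndarray | None = None) -> CableState:
        """One staggered Crank-Nicolson step.

        Gates enter at their half-step values (midpoint of the V update);
        the V system is linear given the gates and solved over the tree.
        ``i_ca_nA`` (positive = inward calcium current magnitude follows
        the electrophysiology sign convention: negative values depolarize)
        is held constant over the step.
        """
        if dt <= 0:
            raise ConfigError("dt must be positive")
        n = len(self.model)
        p = self.params
        g_ion = (self.g_k_max * state.n ** 4
                 + self.g_na_max * state.m ** 3 * state.h + self.g_l)
        e_term = (self.g_k_max * state.n ** 4 * p.e_k
                  + self.g_na_max * state.m ** 3 * state.h * p.e_na
                  + self.g_l * p.e_l)
        if i_ca_nA is None:
            i_ca_nA = self.calcium_current(state)
        i_inj = np.zeros(n)
        if stim is not None:
            comp = stim.compartment
            if comp is None:
                comp = self.model.stimulation_default()
            i_inj[comp] = stim.current(state.t, state.t + dt)
        rhs_current = i_inj - i_ca_nA + e_term
        C = self.capacitance
        A = (sp.diags(C / dt + 0.5 * g_ion) + 0.5 * self.laplacian)
        b = ((C / dt - 0.5 * g_ion) * state.V
             - 0.5 * (self.laplacian @ state.V) + rhs_current)
        if n <= 256:
            V_new = np.linalg.solve(A.toarray(), b)
        else:
            V_new = spla.spsolve(sp.csc_matrix(A), b)
        if not np.all(np.isfinite(V_new)):
            raise SolverError(f"cable step diverged at t={state.t} (dt={dt})")
        new = CableState(V=V_new, n=state.n.copy(), m=state.m.copy(),
                         h=state.h.copy(), ca=state.ca.copy(),
                         t=state.t + dt)
        if hasattr(state, "kl"):
            new.kl = vgcc.ChannelState(state.kl.k.copy(), state.kl.l.copy())
        # gates advance one full step centered on V_new (half-step lattice)
        self._advance_gates(new, V_new, dt)
        return new

    def prime_gates(self, state: CableState, dt: float) -> None:
        """Move gates from t=0 to t=dt/2 to start the staggered lattice."""
        self._advance_gates(state, state.V, dt / 2.0)


def run_protocol(model: CompartmentModel | CableModel,
                 params: MembraneParams | None = None,
                 stim: StimProtocol | None = None,
                 T_total: float = 1000.0, dt: float = 0.1,
                 channel: vgcc.BGParams | None = None,
                 ca0_uM: float = 0.1):
    """Run a full stimulation protocol; returns (t, V[time, comp]).

    The time series has T_total/dt + 1 samples per compartment (initial
    condition included).
    """
    if params is None:
        params = MembraneParams()
    cable = model if isinstance(model, CableModel) else \
        CableModel(model, params, channel=channel)
    n_steps = int(round(T_total / dt))
    if abs(n_steps * dt - T_total) > 1e-9 * max(1.0, T_total):
        raise ConfigError("T_total must be an integer multiple of dt")
    state = cable.initial_state(ca0_uM)
    V = np.empty((n_steps + 1, len(cable.model)))
    V[0] = state.V
    cable.prime_gates(state, dt)
    for i in range(n_steps):
        state = cable.step(state, stim, dt)
        V[i + 1] = state.V
    t = np.arange(n_steps + 1) * dt
    return t, V
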