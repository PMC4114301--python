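"""Borg-Graham voltage-gated calcium channel with GHK flux.

The channel carries an activation gate ``k`` and an inactivation-style gate
``l`` with open probability G = k * l^2.  Gate kinetics follow the
Borg-Graham exponential rate law

    alpha_x(V) = K_x * exp( z_x * gamma_x     * (V - V_half_x) * F/RT)
    beta_x(V)  = K_x * exp(-z_x * (1-gamma_x) * (V - V_half_x) * F/RT)

so the steady state x_inf(V) = 1/(1 + exp(-z_x (V - V_half_x) F/RT)) is a
Boltzmann independent of gamma, while gamma shapes the voltage dependence
of the time constant tau_x = 1/(alpha+beta) + tau_x0.

The single-channel flux is the Goldman-Hodgkin-Katz current

    F_GHK(V) = p_Ca z^2 F^2 V / RT * ([Ca]_i - [Ca]_o e^{-zFV/RT})
                                     / (1 - e^{-zFV/RT})

(continuous through V = 0, reversing at the Nernst potential).  The molar
boundary-flux density feeding the 3D diffusion problem is
Phi = -rho * G * F_GHK / (z F), converted to uM*um/ms; the sign convention
makes calcium influx (inward, i.e. negative, current) a positive Phi.

Parameter notes
---------------
The default gate constants are the N-type set (V_half -21/-40 mV,
K 1.7/70 ms^-1, tau_0 1.7/70 ms, gamma 0, z_l +1).  The activation slope
defaults to z_k = 3.4, the steep Borg-Graham N-type value, so the channel
is effectively closed at rest (open probability ~3e-3); a shallower slope
leaves a resting leak that, with no extrusion mechanism in the model,
dominates the spike-evoked influx.  The default permeability
p_Ca = 1e-15 cm^3/s is calibrated so the reference protocol produces
open-channel currents below a picoampere and peak dendritic transients of
a few hundred nM, the scale seen in calcium imaging.  All values are
configurable per gate and per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import FARADAY, f_over_rt, nernst_potential

__all__ = ["BGGate", "BGParams", "ChannelState", "bg_rates",
            "gate_equilibrium", "gate_step_euler", "ghk_flux",
            "boundary_flux", "N_TYPE"]


@dataclass(frozen=True)
class BGGate:
    """One Borg-Graham gate: Boltzmann midpoint V_half [mV], slope z
    (dimensionless valence-like factor), asymmetry gamma in [0,1], base
    rate K [1/ms] and rate-limiting floor tau0 [ms]."""

    v_half: float
    z: float
    gamma: float
    K: float
    tau0: float

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("gate base rate K must be positive")
        if self.tau0 < 0:
            raise ValueError("tau0 must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class BGParams:
    """Full channel parameter block (gates + permeation + density)."""

    gate_k: BGGate
    gate_l: BGGate
    p_ca: float = 1.0e-15          # cm^3/s per channel
    z_ion: int = 2                 # calcium valence
    temperature: float = 300.0     # K
    density: float = 1000.0        # channels / um^2
    exponent_k: int = 1
    exponent_l: int = 2
    single_channel_conductance_pS: float = 60.0   # metadata only

    def with_density(self, rho: float) -> "BGParams":
        return replace(self, density=rho)


#: N-type defaults (see module docstring for the slope/permeability notes)
N_TYPE = BGParams(
    gate_k=BGGate(v_half=-21.0, z=3.4, gamma=0.0, K=1.7, tau0=1.7),
    gate_l=BGGate(v_half=-40.0, z=1.0, gamma=0.0, K=70.0, tau0=70.0),
)


@dataclass
class ChannelState:
    """Per-membrane-vertex gate values, clipped to [0, 1]."""

    k: np.ndarray
    l: np.ndarray

    def __post_init__(self):
        self.k = np.atleast_1d(np.asarray(self.k, float))
        self.l = np.atleast_1d(np.asarray(self.l, float))

    @classmethod
    def at_equilibrium(cls, V, params: BGParams) -> "ChannelState":
        V = np.atleast_1d(np.asarray(V, float))
        k_inf, _ = gate_equilibrium_at(V, params.gate_k, params.temperature)
        l_inf, _ = gate_equilibrium_at(V, params.gate_l, params.temperature)
        return cls(k_inf, l_inf)

    def open_fraction(self, params: BGParams) -> np.ndarray:
        """Gating function G = k^a * l^b (the N-type channel: a=1, b=2)."""
        return self.k ** params.exponent_k * self.l ** params.exponent_l


def bg_rates(V, gate: BGGate, temperature: float = 300.0):
    """Forward/backward rates alpha, beta [1/ms] at potential V [mV]."""
    V = np.asarray(V, float)
    f = f_over_rt(temperature)
    dv = V - gate.v_half
    alpha = gate.K * np.exp(gate.z * gate.gamma * dv * f)
    beta = gate.K * np.exp(-gate.z * (1.0 - gate.gamma) * dv * f)
    return alpha, beta


def gate_equilibrium(alpha, beta, tau0: float = 0.0):
    """Steady state x_inf = alpha/(alpha+beta), tau = 1/(alpha+beta)+tau0."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    s = alpha + beta
    if np.any(s <= 0):
        raise ValueError("degenerate rates: alpha + beta must be positive")
    return alpha / s, 1.0 / s + tau0


def gate_equilibrium_at(V, gate: BGGate, temperature: float = 300.0):
    """x_inf and tau_x at potential V, composing the two steps above."""
    return gate_equilibrium(*bg_rates(V, gate, temperature), gate.tau0)


def gate_step_euler(state: ChannelState, V, dt: float,
                    params: BGParams) -> ChannelState:
    """One explicit-Euler step of dx/dt = (x_inf - x)/tau_x per vertex."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = np.asarray(V, float)
    new = {}
    for name, gate in (("k", params.gate_k), ("l", params.gate_l)):
        x = getattr(state, name)
        x_inf, tau = gate_equilibrium_at(V, gate, params.temperature)
        new[name] = np.clip(x + dt * (x_inf - x) / tau, 0.0, 1.0)
    return ChannelState(**new)


def ghk_flux(V, ca_i_uM, ca_o_mM, p_ca: float = 1.0e-15,
             temperature: float = 300.0, z: int = 2) -> np.ndarray:
    """Single-channel GHK current [pA]; negative = calcium influx.

    ``ca_i_uM`` intracellular (uM), ``ca_o_mM`` extracellular (mM),
    ``p_ca`` permeability in cm^3/s.  The removable singularity at V = 0 is
    evaluated by its series limit p_Ca z F ([Ca]_i - [Ca]_o).
    """
    V = np.asarray(V, float)
    ci = np.asarray(ca_i_uM, float) * 1.0e-9    # mol/cm^3
    co = np.asarray(ca_o_mM, float) * 1.0e-6    # mol/cm^3
    u = z * f_over_rt(temperature) * V           # dimensionless
    small = np.abs(u) < 1.0e-6
    u_safe = np.where(small, 1.0, u)
    general = u_safe * (ci - co * np.exp(-u_safe)) / (-np.expm1(-u_safe))
    # series limit at u -> 0, first order
    limit = (ci - co) + u * (ci + co) / 2.0
    amps = p_ca * z * FARADAY * np.where(small, limit, general)
    return amps * 1.0e12    # A -> pA


def reversal_potential(ca_i_uM, ca_o_mM, temperature: float = 300.0,
                       z: int = 2) -> float:
    """Zero-flux (Nernst) potential of the GHK current, mV."""
    return nernst_potential(z, ca_i_uM, ca_o_mM, temperature)


#: pA/um^2 -> uM*um/ms for a divalent ion: 1e6 / (z F)
def _current_to_molar_factor(z: int) -> float:
    return 1.0e6 / (z * FARADAY)


def boundary_flux(V, state: ChannelState, ca_i_uM, ca_o_mM,
                  params: BGParams, density=None) -> np.ndarray:
    """Molar calcium influx density Phi [uM*um/ms] on the membrane.

    Phi = -rho * G * F_GHK / (z F); positive Phi means calcium entering the
    cytosol.  ``density`` may be a scalar or per-vertex array overriding
    ``params.density`` (space-dependent channel distributions).
    """
    rho = params.density if density is None else np.asarray(density, float)
    G = state.open_fraction(params)
    i_pA = ghk_flux(V, ca_i_uM, ca_o_mM, params.p_ca, params.temperature,
                    params.z_ion)
    return -rho * G * i_pA * _current_to_molar_factor(params.z_ion)
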