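"""Conductance-based Hodgkin-Huxley single-neuron dynamics and network coupling.

The neuron model is the classic space-clamped Hodgkin-Huxley membrane
(sodium, potassium and leak currents) written in the modern convention with
the resting potential near -65 mV:

    C dV/dt = I - g_Na m^3 h (V - V_Na) - g_K n^4 (V - V_K)
                - g_l (V - V_l) + I(t)

Each neuron carries a constant depolarizing drive ``I`` that places it in
the tonically firing regime (I around 11 uA/cm^2 gives a period of roughly
14-15 ms), plus a time-varying current ``I(t)`` composed of the synaptic
coupling term and, during stimulation, the evoked stimulation current.

Synaptic output of a neuron is a first-order gate ``s`` driven by a sigmoid
of the presynaptic membrane potential; the coupling current received by
neuron ``i`` is the weighted ensemble average of postsynaptic currents from
all other neurons, with excitatory (+20 mV) or inhibitory (-40 mV) reversal
potential chosen by the sign of the structural connectivity template.

All functions here are pure and vectorised; the engine consumes compiled
versions of the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "V_R_EXC",
    "V_R_INH",
    "NeuronParams",
    "NeuronState",
    "rate_constants",
    "gating_derivatives",
    "gating_steady_state",
    "membrane_derivative",
    "synaptic_gate_derivative",
    "coupling_current",
    "coupling_currents",
    "draw_initial_state",
]

#: Reversal potential of excitatory synaptic coupling (mV).
V_R_EXC = 20.0
#: Reversal potential of inhibitory synaptic coupling (mV).
V_R_INH = -40.0

#: Default intrinsic drive midpoint and half-width (uA/cm^2); each neuron's
#: constant current is drawn uniformly from [I0 - eps, I0 + eps].
I_CONST_MID = 11.0
I_CONST_HALF_WIDTH = 0.45


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters (standard squid-axon values).

    Units: capacitance uF/cm^2, conductances mS/cm^2, potentials mV,
    currents uA/cm^2.
    """

    c_m: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    v_na: float = 50.0
    v_k: float = -77.0
    v_leak: float = -54.4
    i_const: float = I_CONST_MID

    def __post_init__(self) -> None:
        if min(self.c_m, self.g_na, self.g_k, self.g_leak) <= 0:
            raise ValueError("capacitance and conductances must be positive")
        if not self.v_na > self.v_k:
            raise ValueError("V_Na must exceed V_K")


@dataclass
class NeuronState:
    """Per-neuron dynamical variables (arrays of common length N)."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray

    def as_vector(self) -> np.ndarray:
        """Pack into the flat layout [V, m, h, n, s] used by the integrator."""
        return np.concatenate([self.v, self.m, self.h, self.n, self.s])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "NeuronState":
        n = y.size // 5
        parts = y.reshape(5, n)
        return cls(*(parts[k].copy() for k in range(5)))


def _vtrap(x: np.ndarray, scale: float) -> np.ndarray:
    """Numerically safe x / (1 - exp(-x/scale)) (removable singularity at 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        out = x / -np.expm1(-x / scale)
    small = np.abs(x) < 1e-7
    if np.any(small):
        out = np.where(small, scale + np.asarray(x) / 2.0, out)
    return out


def rate_constants(v):
    """Hodgkin-Huxley opening/closing rates at membrane potential ``v`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)`` in 1/ms,
    in the -65 mV resting convention.
    """
    v = np.asarray(v, dtype=float)
    a_m = 0.1 * _vtrap(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def gating_derivatives(v, m, h, n):
    """First-order gating kinetics dx/dt = alpha(V)(1-x) - beta(V)x (1/ms)."""
    a_m, b_m, a_h, b_h, a_n, b_n = rate_constants(v)
    return (
        a_m * (1.0 - m) - b_m * m,
        a_h * (1.0 - h) - b_h * h,
        a_n * (1.0 - n) - b_n * n,
    )


def gating_steady_state(v):
    """Voltage-clamp fixed points x_inf = alpha/(alpha+beta) for m, h, n."""
    a_m, b_m, a_h, b_h, a_n, b_n = rate_constants(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def membrane_derivative(v, m, h, n, params: NeuronParams, i_t=0.0):
    """dV/dt (mV/ms) for membrane state and total time-varying current ``i_t``."""
    i_ion = (
        params.g_na * m**3 * h * (v - params.v_na)
        + params.g_k * n**4 * (v - params.v_k)
        + params.g_leak * (v - params.v_leak)
    )
    return (params.i_const - i_ion + i_t) / params.c_m


def synaptic_gate_derivative(s, v):
    """ds/dt (1/ms): sigmoidal activation by presynaptic V, linear decay."""
    return 0.5 * (1.0 - s) / (1.0 + np.exp(-(v + 5.0) / 12.0)) - 2.0 * s


def coupling_currents(v, s, c, m_template):
    """Coupling current S_i for every neuron (vectorised).

    S_i = N^-1 sum_j (V_r,j - V_i) c_ij |M_ij| s_j, where the synaptic
    reversal potential is +20 mV where the template M_ij is excitatory
    (positive) and -40 mV where it is inhibitory.  Self-terms are excluded
    through the zero diagonal of ``m_template``.
    """
    v = np.asarray(v, float)
    s = np.asarray(s, float)
    c = np.asarray(c, float)
    m = np.asarray(m_template, float)
    if c.shape != m.shape or c.shape[0] != v.size or s.size != v.size:
        raise ValueError("dimension mismatch between states and weights")
    n = v.size
    a = c * np.abs(m)
    vr = np.where(m > 0, V_R_EXC, np.where(m < 0, V_R_INH, 0.0))
    return ((vr * a) @ s - v * (a @ s)) / n


def coupling_current(i, v, s, c, m_template):
    """Coupling current S_i for a single neuron index ``i``."""
    return float(coupling_currents(v, s, c, m_template)[i])


def draw_initial_state(
    n: int,
    rng: np.random.Generator,
    i_mid: float = I_CONST_MID,
    i_half_width: float = I_CONST_HALF_WIDTH,
):
    """Draw random initial conditions for ``n`` neurons.

    V uniform on [-65, 5] mV; m, h, n, s uniform on [0, 1]; per-neuron
    constant drive uniform on [i_mid - i_half_width, i_mid + i_half_width].
    Returns ``(NeuronState, i_const_array)``.
    """
    state = NeuronState(
        v=rng.uniform(-65.0, 5.0, size=n),
        m=rng.uniform(0.0, 1.0, size=n),
        h=rng.uniform(0.0, 1.0, size=n),
        n=rng.uniform(0.0, 1.0, size=n),
        s=rng.uniform(0.0, 1.0, size=n),
    )
    i_const = rng.uniform(i_mid - i_half_width, i_mid + i_half_width, size=n)
    return state, i_const
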