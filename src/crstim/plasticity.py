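"""Mexican-hat connectivity template and event-based STDP.

The network is a one-dimensional chain of N neurons with periodic boundary
conditions.  The structural template M_ij is a Mexican hat of the lattice
distance: short-range connections are excitatory (M > 0), long-range ones
weakly inhibitory (M < 0).  On top of the fixed template sit plastic weights
c_ij in [0, 1], initialised near 0.5, which spike timing-dependent
plasticity (STDP) moves around during the simulation.

STDP is applied event-based: every time a neuron fires, each of its
synapses (incoming and outgoing) is updated once against the partner's most
recent spike, with the asymmetric kernel

    dt >= 0 :  beta1 * exp(-dt / (gamma1 tau))          (potentiation)
    dt <  0 :  beta2 * (dt / tau) * exp(dt / (gamma2 tau))  (depression)

where dt = t_post - t_pre.  Excitatory synapses add +delta*dc, inhibitory
ones -delta*dc, and weights are clipped to [0, 1].  Near-synchronous firing
therefore potentiates the short-range excitatory couplings (kindling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TopologyParams",
    "StdpParams",
    "WeightMatrix",
    "lattice_distance",
    "distance_matrix",
    "mexican_hat",
    "mexican_hat_matrix",
    "init_weights",
    "stdp_delta",
    "on_spike_update",
]


@dataclass(frozen=True)
class TopologyParams:
    """Chain geometry and Mexican-hat shape parameters.

    ``d0`` is the physical length of the chain, so the lattice spacing is
    d = d0/(N-1).  ``wrap`` selects the minimum-image (periodic) distance;
    the plain |i-j| distance is kept as an option for comparison.
    """

    n: int = 200
    d0: float = 10.0
    sigma1: float = 3.5
    sigma2: float = 2.0
    wrap: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two neurons")
        if self.sigma1 <= 0 or self.sigma2 <= 0 or self.d0 <= 0:
            raise ValueError("d0, sigma1, sigma2 must be positive")

    @property
    def spacing(self) -> float:
        """Lattice distance between adjacent neurons, d = d0/(N-1)."""
        return self.d0 / (self.n - 1)


@dataclass(frozen=True)
class StdpParams:
    """STDP kernel constants and learning rate (times in ms)."""

    beta1: float = 1.0
    beta2: float = 16.0
    gamma1: float = 0.12
    gamma2: float = 0.15
    tau: float = 14.0
    delta: float = 0.002

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "gamma1", "gamma2", "tau", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WeightMatrix:
    """Plastic weights ``c`` (in [0,1], zero diagonal) over a signed template ``M``."""

    c: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        if self.c.shape != self.m.shape or self.c.shape[0] != self.c.shape[1]:
            raise ValueError("c and M must be square and of equal shape")

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.m)


def lattice_distance(i, j, topo: TopologyParams):
    """Distance between neurons ``i`` and ``j`` (0-based) in chain units.

    With periodic boundaries the minimum-image convention applies:
    d_ij = d * min(|i-j|, N - |i-j|).
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= topo.n) or np.any(j < 0) or np.any(j >= topo.n):
        raise IndexError("neuron index out of range")
    k = np.abs(i - j)
    if topo.wrap:
        k = np.minimum(k, topo.n - k)
    return topo.spacing * k


def distance_matrix(topo: TopologyParams) -> np.ndarray:
    idx = np.arange(topo.n)
    return lattice_distance(idx[:, None], idx[None, :], topo)


def mexican_hat(i, j, topo: TopologyParams):
    """Signed template M_ij = (1 - d^2/sigma1^2) exp(-d^2/(2 sigma2^2))."""
    d = lattice_distance(i, j, topo)
    return (1.0 - d**2 / topo.sigma1**2) * np.exp(-(d**2) / (2.0 * topo.sigma2**2))


def mexican_hat_matrix(topo: TopologyParams) -> np.ndarray:
    """Full N x N template with the self-connection diagonal zeroed."""
    d = distance_matrix(topo)
    m = (1.0 - d**2 / topo.sigma1**2) * np.exp(-(d**2) / (2.0 * topo.sigma2**2))
    np.fill_diagonal(m, 0.0)
    return m


def init_weights(
    topo: TopologyParams,
    rng: np.random.Generator,
    mean: float = 0.5,
    std: float = 0.01,
) -> np.ndarray:
    """Initial plastic weights: c_ij ~ N(mean, std), clipped to [0,1], zero diagonal."""
    c = rng.normal(mean, std, size=(topo.n, topo.n))
    np.clip(c, 0.0, 1.0, out=c)
    np.fill_diagonal(c, 0.0)
    return c


def stdp_delta(dt, p: StdpParams):
    """STDP kernel value for post-minus-pre lag ``dt`` (ms); dt = 0 potentiates."""
    dt = np.asarray(dt, dtype=float)
    pot = p.beta1 * np.exp(-dt / (p.gamma1 * p.tau))
    dep = p.beta2 * (dt / p.tau) * np.exp(dt / (p.gamma2 * p.tau))
    out = np.where(dt >= 0, pot, dep)
    return out if out.ndim else float(out)


def on_spike_update(
    k: int,
    t_spike: float,
    last_spikes: np.ndarray,
    w: WeightMatrix,
    p: StdpParams,
) -> WeightMatrix:
    """Apply the event-based STDP update triggered by neuron ``k`` spiking.

    ``last_spikes`` holds each neuron's most recent spike time strictly
    before ``t_spike`` (NaN where no spike has occurred yet).  For every
    partner j with a prior spike, the incoming synapse c_kj is updated with
    dt = t_spike - t_j (potentiation branch) and the outgoing synapse c_jk
    with dt = t_j - t_spike (depression branch); the sign of the template
    decides whether delta*dc is added (excitatory) or subtracted
    (inhibitory).  Weights are clipped to [0, 1] in place; the updated
    ``WeightMatrix`` is returned for convenience.
    """
    have = np.isfinite(last_spikes)
    have[k] = False
    if not np.any(have):
        return w
    sgn = w.sign
    dt_in = t_spike - last_spikes[have]  # >= 0
    w.c[k, have] += p.delta * sgn[k, have] * stdp_delta(dt_in, p)
    w.c[have, k] += p.delta * sgn[have, k] * stdp_delta(-dt_in, p)
    np.clip(w.c, 0.0, 1.0, out=w.c)
    np.fill_diagonal(w.c, 0.0)
    return w
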