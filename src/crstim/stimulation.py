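"""Coordinated Reset (CR) stimulation: sequences, schedules and currents.

CR stimulation delivers brief excitatory stimuli through N_s sites placed
along the chain.  Time is organised in ON-cycles of length T_s; within each
ON-cycle every site is activated exactly once, in the order given by a
random permutation ("sequence"), each activation occupying an equal slot of
T_s/N_s.  Two sequence regimes are used:

* RVS (rapidly varying sequence): a fresh random permutation every ON-cycle.
* SVS-n (slowly varying sequence): each random permutation is repeated for n
  consecutive ON-cycles before the next is drawn (n = 100 by default).

A site activation evokes a normalized conductance transient shaped as an
alpha-function with time-to-peak tau_stim = T_s/(6 N_s), which spreads over
the chain with a quadratic spatial decay profile of scale sigma_d = 0.08 d0.
The evoked current in neuron i is excitatory, pulling V toward +20 mV,
scaled by the dimensionless intensity K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .plasticity import TopologyParams, lattice_distance

__all__ = [
    "StimGeometry",
    "StimStage",
    "StimProtocol",
    "SequenceSchedule",
    "default_sites",
    "draw_sequence",
    "sequence_stream",
    "build_schedule",
    "indicator",
    "stim_conductance",
    "spatial_decay",
    "spatial_decay_matrix",
    "stim_current",
]

#: Excitatory reversal potential of the stimulation-evoked current (mV).
V_R_STIM = 20.0


def default_sites(n: int, n_sites: int = 4) -> Tuple[int, ...]:
    """Evenly spaced site positions (0-based neuron indices).

    Site k sits at the centre of the k-th of ``n_sites`` equal blocks; for
    N=200 and 4 sites this gives neurons 24, 74, 124, 174 (numbers 25, 75,
    125, 175 in 1-based counting).
    """
    block = n // n_sites
    return tuple(block // 2 - 1 + k * block for k in range(n_sites))


@dataclass(frozen=True)
class StimGeometry:
    """Stimulation-site layout and spatial decay scale."""

    sites: Tuple[int, ...] = (24, 74, 124, 174)
    sigma_d_factor: float = 0.08  # sigma_d = factor * d0

    def __post_init__(self) -> None:
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError("sites must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sigma_d(self, topo: TopologyParams) -> float:
        return self.sigma_d_factor * topo.d0


@dataclass(frozen=True)
class StimStage:
    """One CR-on stage: sequence mode, intensity, duration and ON/OFF pattern.

    ``mode`` is "RVS" or "SVS"; for SVS each drawn sequence is repeated
    ``svs_repeats`` consecutive ON-cycles.  ``on_off`` = (#ON, #OFF) cycles
    per block; the default (1, 0) means permanent stimulation (no
    OFF-cycles).  ``duration_s`` is in seconds, ``k`` is the dimensionless
    intensity.
    """

    mode: str = "RVS"
    k: float = 0.2
    duration_s: float = 64.0
    svs_repeats: int = 100
    on_off: Tuple[int, int] = (1, 0)

    def __post_init__(self) -> None:
        if self.mode not in ("RVS", "SVS"):
            raise ValueError(f"unknown CR mode {self.mode!r}")
        if self.k < 0:
            raise ValueError("intensity K must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("stage duration must be positive")
        if self.svs_repeats < 1:
            raise ValueError("SVS repeat count must be >= 1")
        if self.on_off[0] < 1 or self.on_off[1] < 0:
            raise ValueError("on_off must have >=1 ON and >=0 OFF cycles")


@dataclass(frozen=True)
class StimProtocol:
    """Ordered CR-on stages plus the ON-cycle length and CR-off duration.

    ``cr_off_s = None`` means the CR-off period lasts as long as the total
    CR-on period.
    """

    stages: Tuple[StimStage, ...] = ()
    t_s: float = 16.0  # ON-cycle length, ms
    cr_off_s: Optional[float] = None

    @property
    def total_on_s(self) -> float:
        return sum(st.duration_s for st in self.stages)

    @property
    def off_s(self) -> float:
        return self.total_on_s if self.cr_off_s is None else self.cr_off_s


@dataclass
class SequenceSchedule:
    """Concrete activation schedule of one stage.

    ``onsets`` (ms) and ``site_idx`` (index into the geometry's site list)
    are parallel arrays sorted by onset; each ON-cycle contributes one
    activation per site.  ``t_start``/``t_end`` bound the stage, ``slot``
    is the activation slot length T_s/N_s.
    """

    onsets: np.ndarray
    site_idx: np.ndarray
    t_start: float
    t_end: float
    t_s: float
    n_sites: int

    @property
    def slot(self) -> float:
        return self.t_s / self.n_sites

    def onsets_of_site(self, k: int) -> np.ndarray:
        """Activation onset times (ms) of site ``k``."""
        return self.onsets[self.site_idx == k]


def draw_sequence(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    """Uniformly random permutation of the site indices 0..N_s-1."""
    return rng.permutation(n_sites)


def sequence_stream(
    mode: str, rng: np.random.Generator, n_sites: int, svs_repeats: int = 100
) -> Iterator[np.ndarray]:
    """Infinite per-ON-cycle permutation stream.

    RVS draws a fresh permutation each cycle; SVS emits every drawn
    permutation ``svs_repeats`` consecutive times.
    """
    if mode == "RVS":
        while True:
            yield draw_sequence(rng, n_sites)
    elif mode == "SVS":
        while True:
            seq = draw_sequence(rng, n_sites)
            for _ in range(svs_repeats):
                yield seq
    else:
        raise ValueError(f"unknown CR mode {mode!r}")


def build_schedule(
    stage: StimStage,
    geom: StimGeometry,
    rng: np.random.Generator,
    t_start: float = 0.0,
    t_s: float = 16.0,
) -> SequenceSchedule:
    """Lay out all site activations of one stage on the time axis.

    The m-th element of a cycle's permutation activates at
    cycle_start + m * T_s/N_s.  OFF-cycles (from the stage's ON/OFF block
    pattern) occupy a full T_s without activations and without consuming a
    sequence from the stream.
    """
    n_sites = geom.n_sites
    slot = t_s / n_sites
    n_cycles = int(round(stage.duration_s * 1000.0 / t_s))
    stream = sequence_stream(stage.mode, rng, n_sites, stage.svs_repeats)
    n_on, n_off = stage.on_off
    block = n_on + n_off
    onsets, sites = [], []
    for cyc in range(n_cycles):
        if block > 1 and (cyc % block) >= n_on:
            continue  # OFF-cycle
        seq = next(stream)
        t0 = t_start + cyc * t_s
        for m, site in enumerate(seq):
            onsets.append(t0 + m * slot)
            sites.append(site)
    return SequenceSchedule(
        onsets=np.asarray(onsets, float),
        site_idx=np.asarray(sites, np.int64),
        t_start=t_start,
        t_end=t_start + n_cycles * t_s,
        t_s=t_s,
        n_sites=n_sites,
    )


def indicator(k: int, t: float, schedule: SequenceSchedule) -> int:
    """1 iff site ``k`` is active at time ``t`` (within its slot), else 0."""
    if t < schedule.t_start or t >= schedule.t_end:
        return 0
    on = schedule.onsets_of_site(k)
    j = np.searchsorted(on, t, side="right") - 1
    if j < 0:
        return 0
    return int(on[j] <= t < on[j] + schedule.slot)


def stim_conductance(t, t_k, tau_stim: float):
    """Normalized alpha-function conductance after an activation at ``t_k``.

    G(t) = ((t-t_k)/tau_stim) exp(-(t-t_k)/tau_stim), zero for t < t_k;
    peaks at G = 1/e when t - t_k = tau_stim.
    """
    x = (np.asarray(t, float) - t_k) / tau_stim
    out = np.where(x >= 0, x * np.exp(-np.clip(x, 0, None)), 0.0)
    return out if out.ndim else float(out)


def spatial_decay(i, k: int, geom: StimGeometry, topo: TopologyParams):
    """Quadratic decay D = 1/(1 + d_ik^2/sigma_d^2) of site k's stimulus at neuron i."""
    d = lattice_distance(i, np.full_like(np.asarray(i), geom.sites[k]), topo)
    sd = geom.sigma_d(topo)
    return 1.0 / (1.0 + d**2 / sd**2)


def spatial_decay_matrix(geom: StimGeometry, topo: TopologyParams) -> np.ndarray:
    """N x N_s matrix of decay profiles, one column per site."""
    idx = np.arange(topo.n)
    return np.column_stack(
        [spatial_decay(idx, k, geom, topo) for k in range(geom.n_sites)]
    )


def stim_current(
    t: float,
    v: np.ndarray,
    k_intensity: float,
    schedule: SequenceSchedule,
    geom: StimGeometry,
    topo: TopologyParams,
) -> np.ndarray:
    """Evoked stimulation current F_i (uA/cm^2) for all neurons at time ``t``.

    F_i = (V_r - V_i) * K * sum_k D(i, x_k) rho_k(t) G_stim(t); with
    sequential activation at most one site is active, and only its most
    recent activation contributes (the alpha-function has decayed to <2% of
    peak by the end of a slot).
    """
    v = np.asarray(v, float)
    f = np.zeros_like(v)
    if k_intensity == 0.0 or not (schedule.t_start <= t < schedule.t_end):
        return f
    tau_stim = schedule.t_s / (6.0 * schedule.n_sites)
    d_mat = spatial_decay_matrix(geom, topo)
    for site in range(schedule.n_sites):
        on = schedule.onsets_of_site(site)
        j = np.searchsorted(on, t, side="right") - 1
        if j < 0 or t >= on[j] + schedule.slot:
            continue
        g = stim_conductance(t, on[j], tau_stim)
        f += (V_R_STIM - v) * k_intensity * d_mat[:, site] * g
    return f
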