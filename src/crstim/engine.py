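"""Protocol orchestration and numerical integration.

The engine integrates the coupled 5N-dimensional system (V, m, h, n, s per
neuron) through the full experiment timeline:

    equilibration (no STDP) -> kindling (STDP only) -> CR-on stages -> CR-off

Time is measured in ms with t = 0 at CR onset (the kindling period occupies
negative times), matching the convention used throughout the analysis layer
and the serialized outputs.

Numerics
--------
Integration uses an adaptive Dormand-Prince Runge-Kutta 4(5) stepper
(relative tolerance 1e-5, absolute tolerance 1e-7 by default), compiled
with numba.  The timeline is cut into short segments - at most one
stimulation slot (T_s/N_s, 4 ms by default) - so that the discontinuous
site-activation indicator never sits inside an adaptive step.  Spikes
(downward crossings of V = 0 mV) are located per accepted step by bisection
on the cubic Hermite interpolant, with a 2 ms minimum inter-spike interval
to suppress numerical double counting.  STDP updates are applied at segment
ends in spike-time order; segments are short relative to the STDP time
constants, so the deferral error is negligible.  Gating variables are
clipped to [0, 1] after each segment to guard tolerance-induced excursions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .model_core import V_R_EXC, V_R_INH, draw_initial_state
from .plasticity import StdpParams, TopologyParams, init_weights, mexican_hat_matrix
from .stimulation import (
    SequenceSchedule,
    StimGeometry,
    StimProtocol,
    StimStage,
    build_schedule,
    spatial_decay_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolTimeline",
    "SimResult",
    "SampleSet",
    "run_protocol",
    "run_samples",
    "detect_spikes",
]

_NO_SPIKE = -1.0e18  # sentinel for "never spiked"
MIN_ISI_MS = 2.0


# --------------------------------------------------------------------------
# compiled kernels
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _rhs(t, y, out, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim):
    """Time derivative of the packed state [V, m, h, n, s].

    ``a_mat`` = c * |M| and ``p_mat`` = V_r * c * |M| are maintained by the
    STDP kernel; the coupling term is S_i = ((P s)_i - V_i (A s)_i)/N.
    A single stimulation site (``d_col`` decay profile, alpha-function onset
    ``onset``) may be active; k_amp <= 0 disables stimulation.
    """
    n = i_const.size
    v = y[:n]
    m = y[n : 2 * n]
    h = y[2 * n : 3 * n]
    ng = y[3 * n : 4 * n]
    s = y[4 * n : 5 * n]
    a_s = np.dot(a_mat, s)
    p_s = np.dot(p_mat, s)
    g = 0.0
    if k_amp > 0.0 and t >= onset:
        x = (t - onset) / tau_stim
        g = x * math.exp(-x)
    for i in range(n):
        vi = v[i]
        # gating rates (classic squid-axon forms, -65 mV resting convention)
        x1 = vi + 40.0
        if abs(x1) < 1e-7:
            am = 0.1 * (10.0 + x1 / 2.0)
        else:
            am = 0.1 * x1 / -math.expm1(-x1 / 10.0)
        bm = 4.0 * math.exp(-(vi + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(vi + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(vi + 35.0) / 10.0))
        x2 = vi + 55.0
        if abs(x2) < 1e-7:
            an = 0.01 * (10.0 + x2 / 2.0)
        else:
            an = 0.01 * x2 / -math.expm1(-x2 / 10.0)
        bn = 0.125 * math.exp(-(vi + 65.0) / 80.0)

        mi = m[i]
        hi = h[i]
        ni = ng[i]
        i_ion = (
            120.0 * mi * mi * mi * hi * (vi - 50.0)
            + 36.0 * ni * ni * ni * ni * (vi + 77.0)
            + 0.3 * (vi + 54.4)
        )
        i_t = (p_s[i] - vi * a_s[i]) / n
        if g > 0.0:
            i_t += (20.0 - vi) * k_amp * d_col[i] * g
        out[i] = i_const[i] - i_ion + i_t
        out[n + i] = am * (1.0 - mi) - bm * mi
        out[2 * n + i] = ah * (1.0 - hi) - bh * hi
        out[3 * n + i] = an * (1.0 - ni) - bn * ni
        out[4 * n + i] = 0.5 * (1.0 - s[i]) / (1.0 + math.exp(-(vi + 5.0) / 12.0)) - 2.0 * s[i]


@njit(cache=True, fastmath=True)
def _hermite_v(theta, h, v0, v1, f0, f1):
    t2 = theta * theta
    t3 = t2 * theta
    return (
        (2.0 * t3 - 3.0 * t2 + 1.0) * v0
        + (t3 - 2.0 * t2 + theta) * h * f0
        + (-2.0 * t3 + 3.0 * t2) * v1
        + (t3 - t2) * h * f1
    )


@njit(cache=True, fastmath=True)
def _integrate_segment(
    y,
    t0,
    t1,
    h_init,
    rtol,
    atol,
    a_mat,
    p_mat,
    i_const,
    k_amp,
    d_col,
    onset,
    tau_stim,
    det_last,
    spike_t,
    spike_i,
    n_spikes,
    rec_times,
    rec_next,
    rec_v,
):
    """Adaptive RK45 over [t0, t1] with spike detection.

    Appends detected spikes to ``spike_t``/``spike_i`` starting at index
    ``n_spikes``; returns (new spike count, suggested next step, rec_next).
    ``rec_times``/``rec_v`` implement optional dense V sampling (rec_next is
    the index of the next sample time >= current t).
    """
    ny = y.size
    n = ny // 5
    k1 = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    k5 = np.empty(ny)
    k6 = np.empty(ny)
    k7 = np.empty(ny)
    ytmp = np.empty(ny)
    ynew = np.empty(ny)
    _rhs(t0, y, k1, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
    t = t0
    h = h_init
    if h <= 0.0:
        h = 0.01
    max_h = t1 - t0
    if h > max_h:
        h = max_h
    while t < t1 - 1e-12:
        if t + h > t1:
            h = t1 - t
        # Dormand-Prince 4(5)
        for i in range(ny):
            ytmp[i] = y[i] + h * (0.2 * k1[i])
        _rhs(t + 0.2 * h, ytmp, k2, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        for i in range(ny):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(t + 0.3 * h, ytmp, k3, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        for i in range(ny):
            ytmp[i] = y[i] + h * (
                44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i]
            )
        _rhs(t + 0.8 * h, ytmp, k4, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        for i in range(ny):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(t + 8.0 / 9.0 * h, ytmp, k5, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        for i in range(ny):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(t + h, ytmp, k6, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        for i in range(ny):
            ynew[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(t + h, ynew, k7, a_mat, p_mat, i_const, k_amp, d_col, onset, tau_stim)
        # error estimate (difference of 5th- and 4th-order solutions)
        err = 0.0
        for i in range(ny):
            e = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            ay0 = abs(y[i])
            ay1 = abs(ynew[i])
            sc = atol + rtol * (ay0 if ay0 > ay1 else ay1)
            r = e / sc
            err += r * r
        err = math.sqrt(err / ny)
        if err <= 1.0 or h <= 1e-10:
            # accepted: spike detection on V components via Hermite root
            for i in range(n):
                v0 = y[i]
                v1 = ynew[i]
                if v0 >= 0.0 and v1 < 0.0:
                    ta = 0.0
                    tb = 1.0
                    for _ in range(40):
                        tm = 0.5 * (ta + tb)
                        vm = _hermite_v(tm, h, v0, v1, k1[i], k7[i])
                        if vm >= 0.0:
                            ta = tm
                        else:
                            tb = tm
                    ts = t + 0.5 * (ta + tb) * h
                    if ts - det_last[i] >= MIN_ISI_MS:
                        spike_t[n_spikes] = ts
                        spike_i[n_spikes] = i
                        n_spikes += 1
                        det_last[i] = ts
            # optional dense V sampling on the accepted step
            while rec_next < rec_times.size and rec_times[rec_next] <= t + h + 1e-12:
                tr = rec_times[rec_next]
                if tr < t - 1e-12:
                    rec_next += 1
                    continue
                th = (tr - t) / h if h > 0 else 0.0
                if th < 0.0:
                    th = 0.0
                if th > 1.0:
                    th = 1.0
                for i in range(n):
                    rec_v[rec_next, i] = _hermite_v(th, h, y[i], ynew[i], k1[i], k7[i])
                rec_next += 1
            t += h
            for i in range(ny):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            if math.isnan(y[0]):
                return -1, h, rec_next
        fac = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h > max_h:
            h = max_h
        if h < 1e-10:
            h = 1e-10
    # clip gating/synaptic variables (guards tolerance-induced excursions)
    for i in range(n, ny):
        if y[i] < 0.0:
            y[i] = 0.0
        elif y[i] > 1.0:
            y[i] = 1.0
    return n_spikes, h, rec_next


@njit(cache=True)
def _apply_stdp(
    spike_t,
    spike_i,
    n_spikes,
    pair_last,
    c,
    a_mat,
    p_mat,
    abs_m,
    sgn_m,
    vr_m,
    beta1,
    beta2,
    gamma1,
    gamma2,
    tau,
    delta,
):
    """Event-based STDP over a segment's spikes, in spike-time order.

    Every spike of neuron k at time t pairs once with each partner's most
    recent prior spike: incoming c[k, j] potentiates (dt >= 0), outgoing
    c[j, k] depresses (dt < 0); the template sign flips the increment for
    inhibitory synapses.  The coupling matrices A = c|M| and P = V_r c|M|
    are updated incrementally.
    """
    n = c.shape[0]
    g1t = gamma1 * tau
    g2t = gamma2 * tau
    for e in range(n_spikes):
        k = spike_i[e]
        t = spike_t[e]
        for j in range(n):
            if j == k:
                continue
            tj = pair_last[j]
            if tj <= _NO_SPIKE:
                continue
            dt = t - tj  # >= 0 by construction
            pot = beta1 * math.exp(-dt / g1t)
            dep = beta2 * (-dt / tau) * math.exp(-dt / g2t)
            ckj = c[k, j] + delta * sgn_m[k, j] * pot
            if ckj < 0.0:
                ckj = 0.0
            elif ckj > 1.0:
                ckj = 1.0
            c[k, j] = ckj
            a_mat[k, j] = ckj * abs_m[k, j]
            p_mat[k, j] = vr_m[k, j] * a_mat[k, j]
            cjk = c[j, k] + delta * sgn_m[j, k] * dep
            if cjk < 0.0:
                cjk = 0.0
            elif cjk > 1.0:
                cjk = 1.0
            c[j, k] = cjk
            a_mat[j, k] = cjk * abs_m[j, k]
            p_mat[j, k] = vr_m[j, k] * a_mat[j, k]
        pair_last[k] = t


# --------------------------------------------------------------------------
# timeline and results
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolTimeline:
    """Durations of the pre-stimulation periods (seconds)."""

    equilibration_s: float = 2.0
    kindling_s: float = 60.0


@dataclass
class SampleSet:
    """Seed pairs defining the batch: (initial-condition seed, sequence seed)."""

    pairs: List[Tuple[int, int]]

    @classmethod
    def default(cls, n: int = 11, base: int = 0) -> "SampleSet":
        return cls([(base + 2 * i + 1, base + 2 * i + 2) for i in range(n)])

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("sample seed pairs must be distinct")


@dataclass
class SimResult:
    """Everything a protocol run produces; times in ms relative to CR onset."""

    spike_times: np.ndarray
    spike_neurons: np.ndarray
    cav_times: np.ndarray
    cav_values: np.ndarray
    weight_snapshots: Dict[str, np.ndarray]
    boundaries: Dict[str, Tuple[float, float]]
    m_template: np.ndarray
    c_final: np.ndarray
    seed_ic: int
    seed_seq: int
    schedules: List[SequenceSchedule]
    config: object = None
    v_rec_times: Optional[np.ndarray] = None
    v_rec: Optional[np.ndarray] = None
    _trains: Optional[List[np.ndarray]] = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return self.m_template.shape[0]

    def spike_trains(self) -> List[np.ndarray]:
        """Per-neuron sorted spike times (ms)."""
        if self._trains is None:
            order = np.argsort(self.spike_times, kind="stable")
            st = self.spike_times[order]
            si = self.spike_neurons[order]
            self._trains = [st[si == i] for i in range(self.n_neurons)]
        return self._trains


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    dv: Optional[np.ndarray] = None,
    min_isi: float = MIN_ISI_MS,
) -> np.ndarray:
    """Spike times of a sampled membrane trace: downward crossings of V = 0.

    Crossing times are located on the interpolant (cubic Hermite when the
    derivative ``dv`` is supplied, linear otherwise); crossings closer than
    ``min_isi`` ms to the previous accepted spike are discarded.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    idx = np.where((v[:-1] >= 0.0) & (v[1:] < 0.0))[0]
    times = []
    for i in idx:
        h = t[i + 1] - t[i]
        if dv is not None:
            ta, tb = 0.0, 1.0
            for _ in range(60):
                tm = 0.5 * (ta + tb)
                vm = _hermite_v(tm, h, v[i], v[i + 1], dv[i], dv[i + 1])
                if vm >= 0.0:
                    ta = tm
                else:
                    tb = tm
            ts = t[i] + 0.5 * (ta + tb) * h
        else:
            ts = t[i] + v[i] / (v[i] - v[i + 1]) * h
        if not times or ts - times[-1] >= min_isi:
            times.append(ts)
    return np.asarray(times)


# --------------------------------------------------------------------------
# protocol driver
# --------------------------------------------------------------------------


def _average_weight(c: np.ndarray, sgn_m: np.ndarray) -> float:
    n = c.shape[0]
    return float(np.sum(sgn_m * c) / n**2)


def run_protocol(config, seed_ic: int, seed_seq: int) -> SimResult:
    """Integrate the full protocol for one sample.

    ``config`` is a :class:`crstim.cli_io.RunConfig` (or any object with the
    same attributes).  The initial-condition RNG (``seed_ic``) draws the
    initial state, intrinsic currents and initial weights; the sequence RNG
    (``seed_seq``) is consumed only by the CR sequence draws, so two samples
    differing only in ``seed_seq`` share the identical kindled network.
    """
    topo: TopologyParams = config.topology
    stdp: StdpParams = config.stdp
    geom: StimGeometry = config.geometry
    protocol: StimProtocol = config.protocol
    n = topo.n

    rng_ic = np.random.default_rng(seed_ic)
    rng_seq = np.random.default_rng(seed_seq)

    state, i_const = draw_initial_state(n, rng_ic)
    c = init_weights(topo, rng_ic, config.init_weight_mean, config.init_weight_std)
    m_template = mexican_hat_matrix(topo)
    abs_m = np.ascontiguousarray(np.abs(m_template))
    sgn_m = np.sign(m_template)
    vr_m = np.where(m_template > 0, V_R_EXC, np.where(m_template < 0, V_R_INH, 0.0))
    a_mat = np.ascontiguousarray(c * abs_m)
    p_mat = np.ascontiguousarray(vr_m * a_mat)
    d_mat = spatial_decay_matrix(geom, topo)
    zeros_col = np.zeros(n)

    t_equil = config.timeline.equilibration_s * 1000.0
    t_kind = config.timeline.kindling_s * 1000.0
    t_start = -(t_equil + t_kind)

    # build the period list: (name, t0, t1, stdp_on, schedule, K)
    periods: List[Tuple[str, float, float, bool, Optional[SequenceSchedule], float]] = []
    periods.append(("equilibration", t_start, -t_kind, False, None, 0.0))
    periods.append(("kindling", -t_kind, 0.0, True, None, 0.0))
    t_cursor = 0.0
    schedules: List[SequenceSchedule] = []
    for si, stage in enumerate(protocol.stages):
        t_next = t_cursor + stage.duration_s * 1000.0
        sched = build_schedule(stage, geom, rng_seq, t_start=t_cursor, t_s=protocol.t_s)
        schedules.append(sched)
        periods.append((f"stage{si + 1}", t_cursor, t_next, True, sched, stage.k))
        t_cursor = t_next
    off_ms = protocol.off_s * 1000.0
    if off_ms > 0:
        periods.append(("cr_off", t_cursor, t_cursor + off_ms, True, None, 0.0))

    tau_stim = protocol.t_s / (6.0 * geom.n_sites)
    slot = protocol.t_s / geom.n_sites
    seg_ms = min(config.seg_ms, slot)

    y = state.as_vector()
    det_last = np.full(n, _NO_SPIKE)
    pair_last = np.full(n, _NO_SPIKE)
    cap = 4096
    seg_spike_t = np.empty(cap)
    seg_spike_i = np.empty(cap, np.int64)
    all_spike_t: List[np.ndarray] = []
    all_spike_i: List[np.ndarray] = []
    cav_times: List[float] = []
    cav_values: List[float] = []
    snapshots: Dict[str, np.ndarray] = {"initial": c.copy()}
    boundaries: Dict[str, Tuple[float, float]] = {}

    # optional dense V recording
    rec_windows = config.record_v_windows or []
    rec_times_all = (
        np.unique(
            np.concatenate(
                [
                    np.arange(math.ceil(w0), math.floor(w1) + 1.0, config.record_v_cadence_ms)
                    for (w0, w1) in rec_windows
                ]
            )
        )
        if rec_windows
        else np.empty(0)
    )
    rec_v = np.full((rec_times_all.size, n), np.nan) if rec_times_all.size else np.empty((0, n))
    rec_next = 0

    h_next = 0.01
    next_cav = math.ceil(t_start / 1000.0) * 1000.0
    for name, t0, t1, stdp_on, sched, k_amp in periods:
        boundaries[name] = (t0, t1)
        logger.info("period %s: t in [%.0f, %.0f) ms, K=%.3g", name, t0, t1, k_amp)
        t = t0
        # slot boundaries of this period's schedule (activation onsets)
        while t < t1 - 1e-9:
            if sched is not None:
                # segment = one activation slot (or the idle span between slots)
                j = int(np.searchsorted(sched.onsets, t + 1e-9, side="right")) - 1
                if j >= 0 and t < sched.onsets[j] + slot - 1e-9:
                    # inside site j's slot; stimulation acts only here
                    t_seg_end = min(sched.onsets[j] + slot, t1)
                    if k_amp > 0.0:
                        site = int(sched.site_idx[j])
                        d_col = d_mat[:, site]
                        onset = float(sched.onsets[j])
                        amp = k_amp
                    else:
                        d_col = zeros_col
                        onset = 0.0
                        amp = 0.0
                else:
                    # idle span (OFF-cycle gap or before the first onset)
                    nxt = t1
                    if j + 1 < sched.onsets.size:
                        nxt = min(nxt, float(sched.onsets[j + 1]))
                    t_seg_end = min(max(nxt, t + 1e-9), t + protocol.t_s, t1)
                    d_col = zeros_col
                    onset = 0.0
                    amp = 0.0
            else:
                t_seg_end = min(t + seg_ms, t1)
                d_col = zeros_col
                onset = 0.0
                amp = 0.0
            ns, h_next, rec_next = _integrate_segment(
                y,
                t,
                t_seg_end,
                h_next,
                config.rtol,
                config.atol,
                a_mat,
                p_mat,
                i_const,
                amp,
                d_col,
                onset,
                tau_stim,
                det_last,
                seg_spike_t,
                seg_spike_i,
                0,
                rec_times_all,
                rec_next,
                rec_v,
            )
            if ns < 0:
                raise FloatingPointError(
                    f"integration produced NaN state at t={t:.3f} ms (period {name})"
                )
            if ns > 0:
                # within-step detection emits spikes in neuron order; restore
                # strict time order before event-based pairing
                order = np.argsort(seg_spike_t[:ns], kind="stable")
                seg_spike_t[:ns] = seg_spike_t[:ns][order]
                seg_spike_i[:ns] = seg_spike_i[:ns][order]
                if stdp_on:
                    _apply_stdp(
                        seg_spike_t,
                        seg_spike_i,
                        ns,
                        pair_last,
                        c,
                        a_mat,
                        p_mat,
                        abs_m,
                        sgn_m,
                        vr_m,
                        stdp.beta1,
                        stdp.beta2,
                        stdp.gamma1,
                        stdp.gamma2,
                        stdp.tau,
                        stdp.delta,
                    )
                else:
                    # keep pairing bookkeeping warm without weight changes
                    for e in range(ns):
                        pair_last[seg_spike_i[e]] = seg_spike_t[e]
                all_spike_t.append(seg_spike_t[:ns].copy())
                all_spike_i.append(seg_spike_i[:ns].copy())
            t = t_seg_end
            if t + 1e-9 >= next_cav:
                cav_times.append(next_cav)
                cav_values.append(_average_weight(c, sgn_m))
                next_cav += 1000.0
        snapshots[name] = c.copy()

    spike_times = (
        np.concatenate(all_spike_t) if all_spike_t else np.empty(0)
    )
    spike_neurons = (
        np.concatenate(all_spike_i) if all_spike_i else np.empty(0, np.int64)
    )
    v_abs_max = np.max(np.abs(y[:n]))
    if v_abs_max > 150.0:
        logger.warning("membrane potential reached %.1f mV", v_abs_max)
    return SimResult(
        spike_times=spike_times,
        spike_neurons=spike_neurons,
        cav_times=np.asarray(cav_times),
        cav_values=np.asarray(cav_values),
        weight_snapshots=snapshots,
        boundaries=boundaries,
        m_template=m_template,
        c_final=c,
        seed_ic=seed_ic,
        seed_seq=seed_seq,
        schedules=schedules,
        config=config,
        v_rec_times=rec_times_all if rec_times_all.size else None,
        v_rec=rec_v if rec_times_all.size else None,
    )


def run_samples(config, samples: SampleSet, raise_on_error: bool = False):
    """Run every (seed_ic, seed_seq) pair; failures are logged, not fatal.

    Returns a list whose entries are :class:`SimResult` or the exception
    raised for that sample.
    """
    results = []
    for seed_ic, seed_seq in samples.pairs:
        try:
            results.append(run_protocol(config, seed_ic, seed_seq))
        except Exception as exc:  # noqa: BLE001 - batch isolation by contract
            if raise_on_error:
                raise
            logger.error("sample (%d, %d) failed: %s", seed_ic, seed_seq, exc)
            results.append(exc)
    return results
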