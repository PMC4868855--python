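"""Outcome measures: synaptic-weight averages, synchrony, phase statistics.

All synchrony measures derive from spike trains through a piecewise-linear
phase: between consecutive spikes t_m and t_{m+1} of a neuron its phase
grows linearly from 0 to 2pi,

    phi_j(t) = 2 pi (t - t_{j,m}) / (t_{j,m+1} - t_{j,m}),

and is undefined before the first and after the last spike (undefined
samples are excluded from circular averages, never zero-filled).

Population synchrony is the Kuramoto order parameter
R e^{i Phi} = N^-1 sum_j e^{i phi_j}; subgroup order parameters restrict
the sum to the 50 neurons nearest each stimulation site.  Stimulus-locked
dynamics are quantified by the cross-trial resetting index E(dt) (circular
mean of a subgroup's phase at lag dt from its site's activation onsets)
and inter-subgroup interactions by the circular-moment indices
lambda^(nu) = |mean e^{i nu theta}| of the phase-difference distribution,
with alpha = [lambda^(4) - lambda^(1)]_+ flagging rectangularly aligned
multi-peak structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "SubgroupDef",
    "phases_at",
    "average_weight",
    "order_parameter",
    "mean_order_parameter",
    "subgroup_order_parameter",
    "subgroup_phase_series",
    "cross_trial_phases",
    "resetting_index",
    "acute_effects",
    "phase_difference_series",
    "phase_difference_histogram",
    "lambda_index",
    "alpha_index",
    "mann_whitney_one_sided",
    "boxplot_stats",
]

#: Default fraction of undefined phase samples above which analyses abort.
MAX_UNDEFINED_FRACTION = 0.10

#: Angular histogram bin width (rad).
HIST_BIN_WIDTH = np.pi / 18.0


@dataclass(frozen=True)
class SubgroupDef:
    """Partition of the chain into contiguous subgroups, one per site."""

    n: int
    n_groups: int = 4

    def __post_init__(self) -> None:
        if self.n % self.n_groups:
            raise ValueError("subgroups must partition the population evenly")

    def indices(self, sg: int) -> np.ndarray:
        """0-based neuron indices of subgroup ``sg`` (0-based)."""
        size = self.n // self.n_groups
        return np.arange(sg * size, (sg + 1) * size)


def phases_at(spike_trains: Sequence[np.ndarray], times: np.ndarray) -> np.ndarray:
    """Piecewise-linear phases, shape (n_neurons, n_times); NaN where undefined."""
    times = np.atleast_1d(np.asarray(times, float))
    out = np.full((len(spike_trains), times.size), np.nan)
    for j, st in enumerate(spike_trains):
        if st.size < 2:
            continue
        idx = np.interp(times, st, np.arange(st.size), left=np.nan, right=np.nan)
        inside = (times >= st[0]) & (times < st[-1])
        frac = np.mod(idx, 1.0)
        out[j, inside] = 2.0 * np.pi * frac[inside]
    return out


def average_weight(c: np.ndarray, m_template: np.ndarray) -> float:
    """Population-averaged signed synaptic weight C_av = N^-2 sum sgn(M) c."""
    n = c.shape[0]
    return float(np.sum(np.sign(m_template) * c) / n**2)


def _circular_mean(phases: np.ndarray, axis=-1, max_undefined=MAX_UNDEFINED_FRACTION):
    """(R, Phi) of exp(i*phi) over ``axis``, excluding NaNs with a cap."""
    phases = np.asarray(phases, float)
    bad = np.isnan(phases)
    n_tot = phases.shape[axis] if phases.ndim else phases.size
    frac_bad = bad.sum(axis=axis) / max(n_tot, 1)
    if np.any(frac_bad > max_undefined):
        raise ValueError(
            f"{float(np.max(frac_bad)):.1%} of phase samples undefined "
            f"(limit {max_undefined:.0%})"
        )
    z = np.nanmean(np.where(bad, np.nan, np.exp(1j * phases)), axis=axis)
    return np.abs(z), np.mod(np.angle(z), 2.0 * np.pi)


def order_parameter(phases: np.ndarray, axis: int = 0):
    """Kuramoto order parameter (R, Phi) over the neuron axis.

    ``phases`` is (n_neurons,) or (n_neurons, n_times); neurons with
    undefined phase are excluded, erroring if more than 10% are undefined
    at any time point.
    """
    return _circular_mean(phases, axis=axis)


def subgroup_order_parameter(phases: np.ndarray, sg: int, groups: SubgroupDef):
    """(R_sg, Phi_sg): order parameter restricted to subgroup ``sg``."""
    return _circular_mean(phases[groups.indices(sg)], axis=0)


def subgroup_phase_series(
    spike_trains: Sequence[np.ndarray],
    sg: int,
    groups: SubgroupDef,
    times: np.ndarray,
):
    """(R_sg(t), Phi_sg(t)) sampled on ``times`` directly from spike trains."""
    sub = [spike_trains[j] for j in groups.indices(sg)]
    return _circular_mean(phases_at(sub, times), axis=0)


def mean_order_parameter(
    spike_trains: Sequence[np.ndarray],
    t0: float,
    t1: float,
    cadence: float = 1.0,
    groups: Optional[SubgroupDef] = None,
    sg: Optional[int] = None,
) -> float:
    """Time-averaged order parameter over the window [t0, t1).

    Samples at ``cadence`` ms; time points where more than 10% of neurons
    have undefined phase (e.g. the trailing interspike interval at the very
    end of a record) are dropped, erroring only if more than 10% of the
    window is lost that way.  Restricts to subgroup ``sg`` when given.
    """
    trains = (
        [spike_trains[j] for j in groups.indices(sg)]
        if groups is not None and sg is not None
        else list(spike_trains)
    )
    times = np.arange(t0, t1, cadence)
    ph = phases_at(trains, times)
    frac_bad = np.isnan(ph).mean(axis=0)
    ok = frac_bad <= MAX_UNDEFINED_FRACTION
    if ok.mean() < 1.0 - MAX_UNDEFINED_FRACTION:
        raise ValueError(
            f"{1 - ok.mean():.1%} of window time points have too many undefined phases"
        )
    r, _ = _circular_mean(ph[:, ok], axis=0)
    return float(np.mean(r))


def cross_trial_phases(
    phi_fn,
    onsets: np.ndarray,
    window: Tuple[float, float] = (-32.0, 32.0),
    cadence: float = 1.0,
    t_valid: Optional[Tuple[float, float]] = None,
):
    """Cross-trial matrix of subgroup phases around stimulus onsets.

    ``phi_fn(times) -> phases`` evaluates the subgroup mean phase;
    ``onsets`` are the activation times of the subgroup's site.  Returns
    ``(lags, matrix)`` with matrix shape (n_kept_onsets, n_lags), phases
    wrapped to [0, 2pi).  Onsets whose window leaves ``t_valid`` are
    dropped (and counted in the log).
    """
    lags = np.arange(window[0], window[1] + cadence / 2, cadence)
    onsets = np.asarray(onsets, float)
    if t_valid is not None:
        keep = (onsets + lags[0] >= t_valid[0]) & (onsets + lags[-1] <= t_valid[1])
        onsets = onsets[keep]
    grid = onsets[:, None] + lags[None, :]
    phases = np.mod(np.asarray(phi_fn(grid.ravel()), float).reshape(grid.shape), 2 * np.pi)
    return lags, phases


def resetting_index(trial_phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """E(dt) = |L^-1 sum_k exp(i Phi_k)| across trials (NaNs excluded)."""
    z = np.nanmean(np.exp(1j * np.asarray(trial_phases, float)), axis=axis)
    return np.abs(z)


def acute_effects(r_pre: float, r_on: float, r_off: float) -> Tuple[float, float]:
    """(acute effect, after-effect) = (1 - R_on/R_pre, 1 - R_off/R_pre).

    Positive values indicate desynchronization relative to the
    pre-stimulation baseline.
    """
    if r_pre <= 0:
        raise ValueError("pre-stimulation synchrony R_pre must be positive")
    return 1.0 - r_on / r_pre, 1.0 - r_off / r_pre


def phase_difference_series(
    phi_j: np.ndarray, phi_k: np.ndarray
) -> np.ndarray:
    """theta_jk samples = Phi_j - Phi_k wrapped to [0, 2pi); NaNs dropped."""
    theta = np.asarray(phi_j, float) - np.asarray(phi_k, float)
    theta = theta[np.isfinite(theta)]
    return np.mod(theta, 2.0 * np.pi)


def phase_difference_histogram(theta: np.ndarray):
    """Angular histogram with pi/18 bins on [0, 2pi); returns (edges, counts)."""
    edges = np.arange(0.0, 2 * np.pi + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH)
    counts, _ = np.histogram(np.mod(theta, 2 * np.pi), bins=edges)
    return edges, counts


def lambda_index(theta: np.ndarray, nu: int) -> float:
    """Circular moment magnitude lambda^(nu) = |P^-1 sum exp(i nu theta)|."""
    theta = np.asarray(theta, float)
    if theta.size == 0:
        raise ValueError("need at least one phase-difference sample")
    return float(np.abs(np.mean(np.exp(1j * nu * theta))))


def alpha_index(theta: np.ndarray) -> float:
    """alpha = [lambda^(4) - lambda^(1)]_+ (half-wave rectified)."""
    return max(lambda_index(theta, 4) - lambda_index(theta, 1), 0.0)


def mann_whitney_one_sided(group_a, group_b) -> Tuple[float, float]:
    """One-sided Mann-Whitney U test of A stochastically smaller than B.

    Uses the exact null distribution for small tie-free samples (both sizes
    <= 12) and the tie-corrected normal approximation otherwise.  Returns
    (U statistic of A, one-sided p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


def boxplot_stats(values) -> Dict[str, object]:
    """Tukey five-number summary with 1.5*IQR whiskers and outliers.

    Quartiles use linear interpolation of order statistics.  Whiskers
    extend to the most extreme data points inside the fences.
    """
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside[0]),
        "whisker_high": float(inside[-1]),
        "outliers": outliers,
    }
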