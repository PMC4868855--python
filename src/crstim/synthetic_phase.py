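"""Synthetic multi-peak phase-difference families and their index curves.

These parametric distributions calibrate the lambda/alpha detection
pipeline.  Two families are defined on l = 1..qZ (q = 4 or 3):

    psi_l(m) = rho_l(m) + xi_l,   rho_l(m) = ((l mod q) - 1) * pi/2 * mu_l(m)

with mu_l(m) = 1 for l <= q*m and 0 otherwise, and jitter xi_l uniform on
[-eps, eps].  The first q*m samples populate q equidistant peaks (step
pi/2); the rest collapse onto a single peak at 0, so x = m/Z interpolates
between a Dirac-type 1-peak distribution (x = 0) and the full multi-peak
pattern (x = 1).

For eps = 0 the index curves have closed forms: the symmetric 4-peak
family gives lambda^(1)(x) = 1 - x, lambda^(4)(x) = 1, alpha(x) = x; the
asymmetric 3-peak family (peaks a quarter-turn apart, so their 4th
harmonics align) gives lambda^(1)(x) = 1 - 2x/3, lambda^(4)(x) = 1,
alpha(x) = 2x/3.  Jitter attenuates the nu-th moment by sin(nu eps)/(nu
eps); eps = pi/4 drives lambda^(4) to zero and hence alpha to ~0 for all x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import alpha_index, lambda_index

__all__ = [
    "SyntheticDistConfig",
    "generate_samples",
    "synthetic_indices",
    "sweep_x",
    "expected_lambda1",
    "expected_lambda4",
]

_MODES = {"4peak": 4, "3peak": 3}


@dataclass(frozen=True)
class SyntheticDistConfig:
    """Parameters of one synthetic distribution draw."""

    mode: str = "4peak"  # "4peak" (symmetric) or "3peak" (asymmetric)
    z: int = 100
    m: int = 100
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {sorted(_MODES)}")
        if not 0 <= self.m <= self.z:
            raise ValueError("peak-mass parameter m must be in [0, Z]")
        if self.epsilon < 0:
            raise ValueError("jitter half-width epsilon must be >= 0")

    @property
    def q(self) -> int:
        return _MODES[self.mode]

    @property
    def x(self) -> float:
        return self.m / self.z


def generate_samples(
    cfg: SyntheticDistConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw the phase multiset {psi_l}, l = 1..qZ.

    With m = 0 (and eps = 0) every sample is 0; with m = Z the samples fill
    q peaks at multiples of pi/2 (including -pi/2) with equal mass.
    """
    q = cfg.q
    l = np.arange(1, q * cfg.z + 1)
    mu = (l <= q * cfg.m).astype(float)
    rho = ((l % q) - 1) * (np.pi / 2.0) * mu
    if cfg.epsilon > 0:
        if rng is None:
            raise ValueError("jittered draws need an rng")
        rho = rho + rng.uniform(-cfg.epsilon, cfg.epsilon, size=rho.size)
    return rho


def synthetic_indices(samples: np.ndarray):
    """(lambda^(1), lambda^(4), alpha) of a phase multiset."""
    return (
        lambda_index(samples, 1),
        lambda_index(samples, 4),
        alpha_index(samples),
    )


def expected_lambda1(mode: str, x: float) -> float:
    """Closed-form eps = 0 first-moment magnitude."""
    return 1.0 - x if mode == "4peak" else 1.0 - 2.0 * x / 3.0


def expected_lambda4(mode: str, x: float) -> float:
    """Closed-form eps = 0 fourth-moment magnitude (peaks align at nu = 4)."""
    return 1.0


def sweep_x(
    mode: str,
    eps_values: Sequence[float],
    z: int = 100,
    n_replicates: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Index curves lambda^(1)(x), lambda^(4)(x), alpha(x) over x = m/Z.

    For eps > 0 each (eps, m) point is averaged over ``n_replicates``
    jitter draws; columns ``*_se`` hold the standard error over replicates
    (0 for the deterministic eps = 0 curves).
    """
    if any(e > 0 for e in eps_values) and rng is None:
        raise ValueError("jittered sweeps need an rng")
    rows = []
    for eps in eps_values:
        reps = n_replicates if eps > 0 else 1
        for m in range(z + 1):
            cfg = SyntheticDistConfig(mode=mode, z=z, m=m, epsilon=eps)
            vals = np.array(
                [synthetic_indices(generate_samples(cfg, rng)) for _ in range(reps)]
            )
            mean = vals.mean(axis=0)
            se = vals.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(3)
            rows.append(
                {
                    "mode": mode,
                    "epsilon": eps,
                    "x": m / z,
                    "lambda1": mean[0],
                    "lambda4": mean[1],
                    "alpha": mean[2],
                    "lambda1_se": se[0],
                    "lambda4_se": se[1],
                    "alpha_se": se[2],
                }
            )
    return pd.DataFrame(rows)
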