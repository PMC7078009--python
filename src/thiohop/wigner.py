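"""Wigner sampling of harmonic ground-state initial conditions.

The Wigner function of the vibrational ground state of a harmonic mode is a
Gaussian in both the dimensionless coordinate q and momentum p, each with
mean 0 and variance 1/2, so sampling is exact: independent normal draws per
mode.  No thermal excitation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PhaseSpacePoint:
    """One sampled nuclear phase-space point with its electronic start state."""

    q: np.ndarray
    p: np.ndarray
    initial_state: str
    seed: int

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ValueError("q and p must have equal length")


def trajectory_seeds(global_seed: int, n: int) -> np.ndarray:
    """Deterministic per-trajectory sub-seeds from one global seed.

    Uses numpy's SeedSequence spawning so any single trajectory can be
    re-run in isolation from its recorded seed.
    """
    ss = np.random.SeedSequence(global_seed)
    return np.array([int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)])


def sample_wigner(modes, n: int, initial_state: str, seed: int):
    """Draw ``n`` phase-space points from the ground-state Wigner density.

    Parameters
    ----------
    modes : list of NormalMode (only the count matters; the ground-state
        Wigner density is mode-independent in dimensionless coordinates)
    n : number of samples (>= 1)
    initial_state : electronic state label stamped on every sample
    seed : global integer seed; per-sample sub-seeds are derived from it

    Returns
    -------
    list of PhaseSpacePoint with q, p ~ N(0, 1/2) independently per mode.
    """
    if n < 1:
        raise ValueError(f"need at least one sample, got n={n}")
    if not modes:
        raise ValueError("modes must be non-empty")
    nm = len(modes)
    sigma = np.sqrt(0.5)
    out = []
    for sub in trajectory_seeds(seed, n):
        rng = np.random.default_rng(sub)
        q = rng.normal(0.0, sigma, nm)
        p = rng.normal(0.0, sigma, nm)
        out.append(PhaseSpacePoint(q=q, p=p, initial_state=initial_state, seed=int(sub)))
    return out
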