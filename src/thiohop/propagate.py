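"""Surface hopping in the spin-mixed (diagonal) basis.

Implements fewest-switches trajectory surface hopping of the SHARC flavor:
classical nuclei on the active diagonal surface (velocity Verlet),
substepped electronic amplitude propagation with the local-diabatization
(wavefunction-overlap) scheme, propagator-based hop probabilities,
energy-based decoherence, and uniform momentum rescaling at hops.

Internal units are atomic (hbar = 1); the public parameter object speaks
fs and Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .vibronic import VibronicModel
from .wigner import PhaseSpacePoint


@dataclass
class PropagationParams:
    """Propagation settings.

    dt_fs : classical nuclear time step (fs)
    substeps : electronic substeps per classical step
    decoherence_C : energy-based decoherence constant (Hartree); 0 disables
    t_max_fs : total propagation time (fs)
    rng_seed : seed of the hop-decision random stream
    frustrated_policy : "continue" (keep momentum) or "reflect" (negate it)
    frozen_nuclei : if True, nuclei are clamped and only amplitudes evolve
    """

    dt_fs: float = 0.5
    substeps: int = 100
    decoherence_C: float = 0.1
    t_max_fs: float = 1000.0
    rng_seed: int = 0
    frustrated_policy: str = "continue"
    frozen_nuclei: bool = False
    step_energy_tol: float = 1e-6   # Hartree; triggers nuclear micro-stepping
    max_refine: int = 3             # refinement levels (4^level micro-steps)

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.decoherence_C < 0:
            raise ValueError("decoherence constant must be non-negative")
        if self.frustrated_policy not in ("continue", "reflect"):
            raise ValueError(f"unknown frustrated policy {self.frustrated_policy!r}")


@dataclass
class TrajectoryFrame:
    """One recorded time point (materialized on demand from the arrays)."""

    t: float                      # fs
    q: np.ndarray
    p: np.ndarray
    diag_energies: np.ndarray     # Hartree
    mch_energies: np.ndarray
    amplitudes: np.ndarray        # complex, diagonal basis
    mch_amplitudes: np.ndarray    # complex, MCH basis
    active_state: int             # diagonal-state index
    mch_assignment: str           # MCH label of the active diagonal state
    e_kin: float
    e_pot: float

    @property
    def e_tot(self) -> float:
        return self.e_kin + self.e_pot


@dataclass
class HopEvent:
    t: float                      # fs
    from_state: str               # MCH label before the hop
    to_state: str                 # MCH label after (attempted, if frustrated)
    from_diag: int
    to_diag: int
    geometry: np.ndarray          # q at the beginning of the hop step
    frustrated: bool
    potential_gap: float          # Hartree, E(to) - E(from) at hop geometry


class Trajectory:
    """Time series of one surface-hopping trajectory (array storage)."""

    def __init__(self, times, q, p, diag_energies, mch_energies, amplitudes,
                 mch_amplitudes, active, mch_labels_series, e_kin, e_pot,
                 hops, params, model, warnings=None):
        self.times = np.asarray(times)                 # fs
        self.q = np.asarray(q)
        self.p = np.asarray(p)
        self.diag_energies = np.asarray(diag_energies)
        self.mch_energies = np.asarray(mch_energies)
        self.amplitudes = np.asarray(amplitudes)
        self.mch_amplitudes = np.asarray(mch_amplitudes)
        self.active = np.asarray(active)               # diagonal indices
        self.mch_labels_series = list(mch_labels_series)
        self.e_kin = np.asarray(e_kin)
        self.e_pot = np.asarray(e_pot)
        self.hops = list(hops)
        self.params = params
        self.model = model
        self.warnings = list(warnings or [])

    def __len__(self):
        return len(self.times)

    @property
    def frames(self):
        return [self.frame(i) for i in range(len(self))]

    def frame(self, i: int) -> TrajectoryFrame:
        return TrajectoryFrame(
            t=float(self.times[i]), q=self.q[i], p=self.p[i],
            diag_energies=self.diag_energies[i],
            mch_energies=self.mch_energies[i],
            amplitudes=self.amplitudes[i],
            mch_amplitudes=self.mch_amplitudes[i],
            active_state=int(self.active[i]),
            mch_assignment=self.mch_labels_series[i],
            e_kin=float(self.e_kin[i]), e_pot=float(self.e_pot[i]))

    # -- convenience -----------------------------------------------------
    def amplitude_populations(self, basis: str = "diag") -> np.ndarray:
        if basis == "diag":
            return np.abs(self.amplitudes) ** 2
        if basis == "mch":
            return np.abs(self.mch_amplitudes) ** 2
        raise ValueError(f"unknown basis {basis!r}")

    def total_energies(self) -> np.ndarray:
        return self.e_kin + self.e_pot

    def energy_drift_per_ps(self) -> float:
        """Secular total-energy drift (Hartree/ps): least-squares slope of
        E_tot over the whole trajectory.

        Successful hops conserve total energy exactly (the potential jump is
        absorbed by the momentum rescaling), so the full series is the right
        window; the symplectic integrator's bounded oscillation averages out
        of the slope.
        """
        slope = np.polyfit(self.times, self.total_energies(), 1)[0]  # Ha/fs
        return abs(slope) * 1000.0

    def max_interhop_energy_error(self) -> float:
        """Largest net |Delta E_tot| accumulated between consecutive hops
        (the hop steps themselves are segment boundaries)."""
        e = self.total_energies()
        dt = self.params.dt_fs
        hop_frames = sorted({int(round(h.t / dt)) for h in self.hops})
        edges = [0] + hop_frames + [len(e) - 1]
        worst = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            lo, hi = a, max(b - 1, a)
            if hi > lo:
                worst = max(worst, abs(float(e[hi] - e[lo])))
        return worst

    def first_hop_time(self, from_label: str, to_label: str):
        """Time (fs) of the first non-frustrated from->to hop, or None."""
        for h in self.hops:
            if not h.frustrated and h.from_state == from_label and h.to_state == to_label:
                return h.t
        return None

    def label_at_times(self, grid_fs, basis: str = "mch"):
        """Active-state labels on an arbitrary time grid (step function)."""
        idx = np.clip(np.searchsorted(self.times, grid_fs, side="right") - 1,
                      0, len(self) - 1)
        if basis == "mch":
            return [self.mch_labels_series[i] for i in idx]
        if basis == "diag":
            return [int(self.active[i]) for i in idx]
        raise ValueError(f"unknown basis {basis!r}")


def loewdin_orthogonalize(S: np.ndarray) -> np.ndarray:
    """Closest unitary to the overlap matrix: T = S (S^dag S)^(-1/2) = U V^dag."""
    U, _, Vh = np.linalg.svd(S)
    return U @ Vh


def rescale_momentum(p, e_gap, policy="continue", frequencies=None):
    """Uniformly rescale the momentum vector to absorb a potential jump.

    The kinetic energy is sum_i (w_i/2) p_i^2 in dimensionless mode
    coordinates (``frequencies`` defaults to ones).  If it covers ``e_gap``
    the momentum is scaled by sqrt(1 - e_gap/e_kin) along its own
    direction; otherwise the hop is frustrated and ``policy`` applies.

    Returns (p_new, frustrated).
    """
    p = np.asarray(p, dtype=float)
    w = np.ones_like(p) if frequencies is None else np.asarray(frequencies)
    e_kin = 0.5 * np.sum(w * p * p)
    if e_gap == 0:
        return p.copy(), False
    if e_kin > 0 and e_kin >= e_gap:
        return p * np.sqrt(1.0 - e_gap / e_kin), False
    if e_gap < 0 and e_kin == 0:
        # no momentum direction to deposit the released energy into
        return p.copy(), True
    return (-p if policy == "reflect" else p.copy()), True


def apply_decoherence(amplitudes, diag_energies, active, e_kin, C, dt):
    """Energy-based decoherence: damp non-active amplitudes.

    c_k *= exp(-dt / tau_k) with tau_k = (1/|E_k - E_active|)(1 + C/e_kin)
    (hbar = 1); the active amplitude is rescaled to restore unit norm and
    all relative phases are preserved.  Skipped when e_kin <= 0.
    """
    c = np.asarray(amplitudes, dtype=complex).copy()
    if e_kin <= 0 or C < 0:
        return c
    de = np.abs(diag_energies - diag_energies[active])
    for k in range(len(c)):
        if k == active or de[k] == 0:
            continue
        tau = (1.0 / de[k]) * (1.0 + C / e_kin)
        c[k] *= np.exp(-dt / tau)
    pop_others = np.sum(np.abs(c) ** 2) - np.abs(c[active]) ** 2
    pa = np.abs(c[active]) ** 2
    if pa > 0:
        c[active] *= np.sqrt(max(1.0 - pop_others, 0.0) / pa)
    return c


def hop_decision(c_before, c_after, step_propagator, active, rng):
    """Fewest-switches hop decision from the local-diabatization propagator.

    The decrease of the active population over the classical step is
    apportioned among target states via the cross terms of the step
    propagator A (c_after = A c_before):

        P_beta = (1 - |c'_a|^2 / |c_a|^2)
                 * max(0, Re(c'_beta A*_{beta,a} c*_a)) / N,
        N = |c_a|^2 - Re(c'_a A*_{a,a} c*_a),

    clamped at zero and capped so the total never exceeds the actual
    population loss.  One uniform variate against the cumulative
    probabilities picks the target.  Returns (target or None, probabilities).
    """
    c0 = np.asarray(c_before, dtype=complex)
    c1 = np.asarray(c_after, dtype=complex)
    A = np.asarray(step_propagator, dtype=complex)
    n = len(c0)
    probs = np.zeros(n)
    pa0 = np.abs(c0[active]) ** 2
    pa1 = np.abs(c1[active]) ** 2
    if pa0 <= 0 or pa1 >= pa0:
        return None, probs
    loss = 1.0 - pa1 / pa0
    denom = pa0 - np.real(c1[active] * np.conj(A[active, active]) * np.conj(c0[active]))
    if denom <= 0:
        return None, probs
    for b in range(n):
        if b == active:
            continue
        num = np.real(c1[b] * np.conj(A[b, active]) * np.conj(c0[active]))
        probs[b] = loss * max(num, 0.0) / denom
    total = probs.sum()
    if total > loss:
        probs *= loss / total
    r = rng.uniform()
    cum = 0.0
    for b in range(n):
        cum += probs[b]
        if r < cum:
            return b, probs
    return None, probs


def propagate_trajectory(model: VibronicModel, init: PhaseSpacePoint,
                         params: PropagationParams) -> Trajectory:
    """Propagate one surface-hopping trajectory.

    The electronic wavefunction starts as the requested pure MCH state
    expressed in the diagonal basis; the initially active surface is the
    diagonal state of largest initial population.
    """
    dt = params.dt_fs * units.AUT_PER_FS
    nsteps = int(round(params.t_max_fs / params.dt_fs))
    w = model.frequencies
    warnings_log = []

    q = init.q.astype(float).copy()
    p = init.p.astype(float).copy()
    if len(q) != model.nmodes:
        raise ValueError("initial condition does not match the model's modes")
    es = model.evaluate(q)

    start_mch = model.state_index(init.initial_state)
    n = model.nstates
    psi_mch = np.zeros(n, dtype=complex)
    psi_mch[start_mch] = 1.0
    c = es.transform.conj().T @ psi_mch
    active = int(np.argmax(np.abs(c) ** 2))

    rng = np.random.default_rng(params.rng_seed)
    rec = {k: [] for k in ("t", "q", "p", "ed", "em", "c", "cm",
                           "act", "lab", "ekin", "epot")}
    hops = []

    # substep weights for linear interpolation of the diagonal energies
    frac = (np.arange(params.substeps) + 0.5) / params.substeps
    w_old = np.sum(1.0 - frac)
    w_new = np.sum(frac)
    ddt = dt / params.substeps

    def record(t_fs):
        rec["t"].append(t_fs)
        rec["q"].append(q.copy())
        rec["p"].append(p.copy())
        rec["ed"].append(es.diag_energies.copy())
        rec["em"].append(es.mch_energies.copy())
        rec["c"].append(c.copy())
        rec["cm"].append(es.transform @ c)
        rec["act"].append(active)
        rec["lab"].append(es.mch_labels[es.mch_parent(active)])
        rec["ekin"].append(0.5 * np.sum(w * p * p))
        rec["epot"].append(float(es.diag_energies[active]))

    record(0.0)
    for step in range(nsteps):
        q_old = q.copy()
        es_old = es
        e_old = es_old.diag_energies

        if not params.frozen_nuclei:
            e_ref = 0.5 * np.sum(w * p * p) + e_old[active]
            p_half = p - 0.5 * dt * es_old.gradients[active]
            q = q + dt * w * p_half
            es = model.evaluate(q, prev_eigenvectors=es_old.eigenvectors)
            p = p_half - 0.5 * dt * es.gradients[active]
            # The active diagonal surface has sharp avoided crossings where
            # the spin-orbit (or a small vibronic) coupling is narrow; one
            # Verlet step across the kink violates energy conservation.
            # Redo such steps with 4^level velocity-Verlet micro-steps; the
            # electronic propagation and hop test stay on the dt grid.
            err = abs(0.5 * np.sum(w * p * p) + es.diag_energies[active] - e_ref)
            if err > params.step_energy_tol:
                p_orig = p_half + 0.5 * dt * es_old.gradients[active]
                for level in range(1, params.max_refine + 1):
                    nsub = 4 ** level
                    h = dt / nsub
                    qq = q_old.copy()
                    pp = p_orig.copy()
                    _, g = model.active_energy_gradient(qq, active)
                    for _ in range(nsub):
                        pp = pp - 0.5 * h * g
                        qq = qq + h * w * pp
                        ev, g = model.active_energy_gradient(qq, active)
                        pp = pp - 0.5 * h * g
                    err = abs(0.5 * np.sum(w * pp * pp) + ev[active] - e_ref)
                    if err <= params.step_energy_tol or level == params.max_refine:
                        q = qq
                        es = model.evaluate(q, prev_eigenvectors=es_old.eigenvectors)
                        p = pp
                        break
        else:
            es = model.evaluate(q, prev_eigenvectors=es_old.eigenvectors)

        # --- electronic step: local diabatization ---
        S = es_old.eigenvectors.conj().T @ es.eigenvectors
        if np.max(np.abs(S), axis=1).min() < 0.5:
            warnings_log.append(
                f"step {step}: eigenvector tracking overlap below 0.5; "
                "continuing with best-overlap assignment")
        T = loewdin_orthogonalize(S)
        phase = -(w_old * e_old + w_new * es.diag_energies) * ddt
        A = T.conj().T * np.exp(1j * phase)[None, :]  # T^dag @ diag(e^{i phase})
        c_new = A @ c

        # --- hop decision ---
        target, _ = hop_decision(c, c_new, A, active, rng)
        c = c_new
        e_kin = 0.5 * np.sum(w * p * p)
        if target is not None:
            gap = float(es.diag_energies[target] - es.diag_energies[active])
            p_new, frustrated = rescale_momentum(
                p, gap, policy=params.frustrated_policy, frequencies=w)
            hops.append(HopEvent(
                t=(step + 1) * params.dt_fs,
                from_state=es.mch_labels[es.mch_parent(active)],
                to_state=es.mch_labels[es.mch_parent(target)],
                from_diag=active, to_diag=target,
                geometry=q_old.copy(), frustrated=frustrated,
                potential_gap=gap,
            ))
            if not frustrated:
                p = p_new
                active = target
                e_kin = 0.5 * np.sum(w * p * p)

        # --- decoherence ---
        if params.decoherence_C > 0:
            if e_kin > 0:
                c = apply_decoherence(c, es.diag_energies, active, e_kin,
                                      params.decoherence_C, dt)
            else:
                warnings_log.append(f"step {step}: zero kinetic energy, "
                                    "decoherence correction skipped")

        record((step + 1) * params.dt_fs)

    return Trajectory(
        times=np.array(rec["t"]), q=np.array(rec["q"]), p=np.array(rec["p"]),
        diag_energies=np.array(rec["ed"]), mch_energies=np.array(rec["em"]),
        amplitudes=np.array(rec["c"]), mch_amplitudes=np.array(rec["cm"]),
        active=np.array(rec["act"]), mch_labels_series=rec["lab"],
        e_kin=np.array(rec["ekin"]), e_pot=np.array(rec["epot"]),
        hops=hops, params=params, model=model, warnings=warnings_log)


def propagate_ensemble(model, inits, params, progress=False):
    """Propagate a list of initial conditions.

    Each trajectory's hop-decision stream is seeded from its recorded
    initial-condition seed, so any member is re-runnable in isolation.
    """
    trajs = []
    it = inits
    if progress:  # pragma: no cover
        try:
            from tqdm import tqdm
            it = tqdm(inits, desc="trajectories")
        except ImportError:
            pass
    for ic in it:
        par = PropagationParams(
            dt_fs=params.dt_fs, substeps=params.substeps,
            decoherence_C=params.decoherence_C, t_max_fs=params.t_max_fs,
            rng_seed=ic.seed, frustrated_policy=params.frustrated_policy,
            frozen_nuclei=params.frozen_nuclei)
        trajs.append(propagate_trajectory(model, ic, par))
    return trajs
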