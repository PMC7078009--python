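"""Scripted synthetic ensembles with hand-specifiable hop sequences.

These are oracle fixtures: tiny trajectories whose active-state history and
hop list are written down directly (no propagation), so every ensemble
statistic computed from them can be verified by hand.
"""

from __future__ import annotations

import numpy as np

from .propagate import HopEvent, PropagationParams, Trajectory


def scripted_trajectory(model, script=(), t_max_fs=100.0, dt_fs=1.0,
                        initial="S2", q_of_t=None):
    """Build a trajectory whose hops follow ``script``.

    script : iterable of (t_fs, from_label, to_label); hop times are snapped
        to the frame grid.  The active state follows the script; electronic
        amplitudes are kept one-hot on the active state.
    q_of_t : optional callable t_fs -> q vector (defaults to the origin).
    """
    labels = model.state_labels
    n = model.nstates
    nm = model.nmodes
    times = np.arange(0.0, t_max_fs + 0.5 * dt_fs, dt_fs)
    script = sorted(script, key=lambda s: s[0])

    active_label = initial
    act, labs, amps, qs = [], [], [], []
    hops = []
    si = 0
    for t in times:
        while si < len(script) and script[si][0] <= t + 1e-9:
            t_hop, a, b = script[si]
            if a != active_label:
                raise ValueError(f"script hop {a}->{b} at {t_hop} fs does not "
                                 f"start from the active state {active_label}")
            q_hop = (np.zeros(nm) if q_of_t is None
                     else np.asarray(q_of_t(max(t_hop - dt_fs, 0.0))))
            hops.append(HopEvent(t=t_hop, from_state=a, to_state=b,
                                 from_diag=labels.index(a),
                                 to_diag=labels.index(b),
                                 geometry=q_hop, frustrated=False,
                                 potential_gap=0.0))
            active_label = b
            si += 1
        k = labels.index(active_label)
        act.append(k)
        labs.append(active_label)
        c = np.zeros(n, dtype=complex)
        c[k] = 1.0
        amps.append(c)
        qs.append(np.zeros(nm) if q_of_t is None else np.asarray(q_of_t(t)))

    nt = len(times)
    zeros_state = np.zeros((nt, n))
    return Trajectory(
        times=times, q=np.asarray(qs), p=np.zeros((nt, nm)),
        diag_energies=zeros_state, mch_energies=zeros_state,
        amplitudes=np.asarray(amps), mch_amplitudes=np.asarray(amps),
        active=np.asarray(act), mch_labels_series=labs,
        e_kin=np.zeros(nt), e_pot=np.zeros(nt),
        hops=hops, params=PropagationParams(dt_fs=dt_fs, t_max_fs=t_max_fs),
        model=model)


def three_trajectory_ensemble(model):
    """The hand-checkable three-member ensemble used across the tests:

    * trajectory 1 stays in S2;
    * trajectory 2 hops S2->S1 at 10 fs;
    * trajectory 3 hops S2->S1 at 20 fs and back S1->S2 at 30 fs.

    Hand-computed facts: P(S1) = 1/3 for t >= 10 except 2/3 on [20, 30);
    hop matrix counts S2->S1 = 2, S1->S2 = 1; the first S2->S1 hops occur
    at 10 and 20 fs (mean 15 fs, n = 2).
    """
    return [
        scripted_trajectory(model),
        scripted_trajectory(model, [(10.0, "S2", "S1")]),
        scripted_trajectory(model, [(20.0, "S2", "S1"), (30.0, "S1", "S2")]),
    ]
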