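"""Surface-hopping propagator: oracles, conservation laws, bookkeeping."""

import numpy as np
import pytest
from scipy.linalg import expm

import thiohop as th
from thiohop import units
from thiohop.propagate import (apply_decoherence, hop_decision,
                               rescale_momentum)
from thiohop.wigner import PhaseSpacePoint

from conftest import two_state_model


class TestUncoupledLimit:
    def test_active_state_and_amplitude_constant(self):
        cfg = th.default_model_config()
        cfg["kappa_eV"] = {}   # parallel surfaces: no crossings at all
        cfg["lambda_eV"] = {}
        cfg["soc_eV"] = {}
        m = th.build_lvc_model(cfg)
        ic = th.sample_wigner(m.modes, 1, "S2", seed=3)[0]
        tr = th.propagate_trajectory(
            m, ic, th.PropagationParams(t_max_fs=100.0))
        assert len(tr.hops) == 0
        assert np.all(tr.active == tr.active[0])
        k = int(tr.active[0])
        pops = tr.amplitude_populations("diag")
        assert np.all(np.abs(pops[:, k] - 1.0) < 1e-10)
        assert set(tr.mch_labels_series) == {"S2"}


class TestHarmonicOracle:
    """Single-surface motion against the closed-form harmonic solution."""

    @staticmethod
    def _run(dt_fs, q0=0.7, p0=-0.4, t_max=100.0):
        m = two_state_model(gap_ev=2.0, freq_cm1=1000.0)
        ic = PhaseSpacePoint(q=np.array([q0]), p=np.array([p0]),
                             initial_state="A", seed=0)
        par = th.PropagationParams(dt_fs=dt_fs, t_max_fs=t_max,
                                   decoherence_C=0.0,
                                   step_energy_tol=np.inf)
        tr = th.propagate_trajectory(m, ic, par)
        w = m.frequencies[0]
        t_au = tr.times * units.AUT_PER_FS
        q_exact = q0 * np.cos(w * t_au) + p0 * np.sin(w * t_au)
        return np.abs(tr.q[:, 0] - q_exact).max()

    def test_closed_form_and_quadratic_convergence(self):
        err_h = self._run(0.5)
        err_h2 = self._run(0.25)
        assert err_h < 2e-2
        ratio = err_h / err_h2
        assert 3.0 < ratio < 5.0  # global O(dt^2)


class TestQuantumOracle:
    def test_rabi_oscillation_matches_exact_propagation(self):
        """Frozen nuclei, degenerate singlet-triplet pair with constant SOC:
        the MCH populations must follow the exact two-level evolution
        (a Rabi cycle of period pi/V in the populations)."""
        v_ev = 0.02
        m = two_state_model(gap_ev=0.0, soc_ev=v_ev, multiplicities=(1, 3))
        ic = PhaseSpacePoint(q=np.zeros(1), p=np.zeros(1),
                             initial_state="A", seed=0)
        par = th.PropagationParams(dt_fs=0.5, t_max_fs=100.0,
                                   decoherence_C=0.0, frozen_nuclei=True)
        tr = th.propagate_trajectory(m, ic, par)
        pops = tr.amplitude_populations("mch")

        V = v_ev * units.HARTREE_PER_EV
        H = np.array([[0.0, V], [V, 0.0]], dtype=complex)
        for i, t_fs in enumerate(tr.times):
            U = expm(-1j * H * t_fs * units.AUT_PER_FS)
            exact = np.abs(U[:, 0]) ** 2
            assert np.abs(pops[i] - exact).max() < 1e-6

        period_fs = (np.pi / V) * units.FS_PER_AUT
        j = int(round(period_fs / 0.5))
        if j < len(tr.times):
            assert pops[j, 0] == pytest.approx(1.0, abs=1e-4)


class TestHopDecision:
    def test_no_flux_no_hop(self):
        rng = np.random.default_rng(0)
        c = np.array([np.sqrt(0.7), np.sqrt(0.3)], dtype=complex)
        A = np.eye(2, dtype=complex)
        target, probs = hop_decision(c, c, A, 0, rng)
        assert target is None
        assert np.all(probs == 0)

    def test_growing_active_population_gives_zero(self):
        rng = np.random.default_rng(0)
        c0 = np.array([0.6, 0.8], dtype=complex)
        c1 = np.array([0.8, 0.6], dtype=complex)
        target, probs = hop_decision(c0, c1, np.eye(2, dtype=complex), 0, rng)
        assert target is None and np.all(probs == 0)

    def test_negative_flux_clamped(self):
        """A target whose cross term is negative gets probability zero even
        though the active population decreased."""
        rng = np.random.default_rng(0)
        A = np.eye(3, dtype=complex)
        A[0, 0] = 0.95
        A[2, 0] = -0.01
        c0 = np.array([0.9, 0.1, 0.4], dtype=complex)
        c1 = A @ c0
        target, probs = hop_decision(c0, c1, A, 0, rng)
        assert np.all(probs == 0)
        assert target is None

    def test_small_transfer_matches_substep_flux_accumulation(self):
        """Probability agrees with brute-force per-substep Tully flux."""
        V = 1e-4  # a.u.
        delta = 5e-4
        H = np.array([[0.0, V], [V, delta]], dtype=complex)
        dt = 0.5 * units.AUT_PER_FS
        c0 = np.array([1.0, 0.0], dtype=complex)
        A = expm(-1j * H * dt)
        c1 = A @ c0
        rng = np.random.default_rng(1)
        _, probs = hop_decision(c0, c1, A, 0, rng)

        nsub = 2000
        Us = expm(-1j * H * dt / nsub)
        c = c0.copy()
        acc = 0.0
        for _ in range(nsub):
            cn = Us @ c
            dpa = np.abs(c[0]) ** 2 - np.abs(cn[0]) ** 2
            if dpa > 0:
                acc += dpa / np.abs(c[0]) ** 2
            c = cn
        assert probs[1] == pytest.approx(acc, abs=1e-4)


class TestDecoherence:
    def test_pure_active_state_unchanged(self):
        c = np.array([1.0, 0.0, 0.0], dtype=complex)
        out = apply_decoherence(c, np.array([0.0, 0.1, 0.2]), 0,
                                e_kin=0.05, C=0.1, dt=1.0)
        assert np.allclose(out, c)

    def test_decoherence_time_formula(self):
        """|dE| = 0.1, e_kin = 0.1, C = 0.1 (a.u.) -> tau = 20 a.u."""
        dt = 2.0
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        out = apply_decoherence(c, np.array([0.0, 0.1]), 0,
                                e_kin=0.1, C=0.1, dt=dt)
        assert abs(out[1]) / abs(c[1]) == pytest.approx(np.exp(-dt / 20.0),
                                                        rel=1e-12)

    def test_renormalization_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = rng.normal(size=4) + 1j * rng.normal(size=4)
            c /= np.linalg.norm(c)
            out = apply_decoherence(c, rng.normal(size=4), 1,
                                    e_kin=0.02, C=0.1, dt=1.0)
            assert abs(np.sum(np.abs(out) ** 2) - 1.0) < 1e-12

    def test_relative_phases_preserved(self):
        c = np.array([0.8 * np.exp(1j * 0.3), 0.6 * np.exp(1j * 1.1)])
        out = apply_decoherence(c, np.array([0.0, 0.2]), 0,
                                e_kin=0.05, C=0.1, dt=1.0)
        assert np.angle(out[0]) == pytest.approx(0.3)
        assert np.angle(out[1]) == pytest.approx(1.1)


class TestMomentumRescaling:
    def test_zero_gap_identity(self):
        p = np.array([0.3, -0.4])
        p2, frus = rescale_momentum(p, 0.0)
        assert np.array_equal(p2, p) and not frus

    def test_forbidden_hop_frustrated(self):
        p = np.array([0.1])
        p2, frus = rescale_momentum(p, 1.0)
        assert frus and np.array_equal(p2, p)
        p3, frus3 = rescale_momentum(p, 1.0, policy="reflect")
        assert frus3 and np.array_equal(p3, -p)

    def test_rescale_factor(self):
        p = np.array([np.sqrt(0.4)])  # e_kin = 0.2 with unit frequency
        p2, frus = rescale_momentum(p, 0.15)
        assert not frus
        assert np.linalg.norm(p2) / np.linalg.norm(p) == pytest.approx(0.5)

    def test_kinetic_energy_balance_exact(self):
        rng = np.random.default_rng(3)
        w = np.array([0.002, 0.01, 0.02])
        for _ in range(50):
            p = rng.normal(size=3)
            e_kin = 0.5 * np.sum(w * p * p)
            gap = rng.uniform(-0.5, 1.0) * e_kin
            p2, frus = rescale_momentum(p, gap, frequencies=w)
            if not frus:
                e2 = 0.5 * np.sum(w * p2 * p2)
                assert e2 == pytest.approx(e_kin - gap, abs=1e-10)


@pytest.fixture(scope="module")
def traj(default_model):
    ic = th.sample_wigner(default_model.modes, 1, "S2", seed=42)[0]
    return th.propagate_trajectory(
        default_model, ic, th.PropagationParams(t_max_fs=300.0))


class TestTrajectoryInvariants:

    def test_amplitude_norm_unit(self, traj):
        norms = np.sum(np.abs(traj.amplitudes) ** 2, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-8

    def test_norm_conserved_without_decoherence(self, default_model):
        ic = th.sample_wigner(default_model.modes, 1, "S2", seed=5)[0]
        tr = th.propagate_trajectory(
            default_model, ic,
            th.PropagationParams(t_max_fs=100.0, decoherence_C=0.0))
        norms = np.sum(np.abs(tr.amplitudes) ** 2, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-8

    def test_hop_list_bookkeeping(self, traj):
        """The final active surface equals the initial one transformed by
        the ordered list of successful hops."""
        state = int(traj.active[0])
        for h in traj.hops:
            if not h.frustrated:
                assert h.from_diag == state
                state = h.to_diag
        assert state == int(traj.active[-1])

    def test_hops_on_frame_boundaries(self, traj):
        dt = traj.params.dt_fs
        for h in traj.hops:
            assert h.t / dt == pytest.approx(round(h.t / dt))

    def test_energy_conservation(self, traj):
        assert traj.max_interhop_energy_error() < 1e-4
        assert traj.energy_drift_per_ps() < 1e-4

    def test_frames_view_consistent(self, traj):
        fr = traj.frame(10)
        assert fr.e_tot == pytest.approx(fr.e_kin + fr.e_pot)
        assert fr.t == traj.times[10]


def test_convergence_under_step_halving(default_model):
    """Halving dt while doubling the substeps leaves the final electronic
    populations nearly unchanged (hop-free window)."""
    ic = th.sample_wigner(default_model.modes, 1, "S2", seed=8)[0]
    runs = []
    for dt, sub in ((0.25, 200), (0.125, 400)):
        par = th.PropagationParams(dt_fs=dt, substeps=sub, t_max_fs=20.0)
        tr = th.propagate_trajectory(default_model, ic, par)
        assert len([h for h in tr.hops if not h.frustrated]) == 0
        runs.append(np.abs(tr.amplitudes[-1]) ** 2)
    assert np.abs(runs[0] - runs[1]).max() < 1e-3


def test_zero_kinetic_energy_skips_decoherence():
    m = two_state_model(gap_ev=1.0, soc_ev=0.01, multiplicities=(1, 3))
    ic = PhaseSpacePoint(q=np.zeros(1), p=np.zeros(1),
                         initial_state="A", seed=0)
    par = th.PropagationParams(t_max_fs=5.0, frozen_nuclei=True)
    tr = th.propagate_trajectory(m, ic, par)
    assert any("decoherence" in w for w in tr.warnings)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        th.PropagationParams(dt_fs=0.0)
    with pytest.raises(ValueError):
        th.PropagationParams(substeps=0)
    with pytest.raises(ValueError):
        th.PropagationParams(frustrated_policy="bounce")
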