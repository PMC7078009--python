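"""Normal-mode projections, phase alignment, coherence, bond lengths."""

import numpy as np
import pytest

import thiohop as th
from thiohop import units
from thiohop.fixtures import scripted_trajectory
from thiohop.structure import projection_vector
from thiohop.vibronic import IN_PLANE, OUT_OF_PLANE, NormalMode

from conftest import q_for_projection, synthetic_modes


def _mode(index, vec, character):
    return NormalMode(index=index, frequency=0.01,
                      displacement=np.asarray(vec, dtype=float),
                      character=character,
                      reduced_mass=1.0 * units.AMU_TO_AU)


@pytest.fixture
def abc_modes():
    """Three orthonormal single-atom-component modes: 7 and 8 out-of-plane
    (z of atoms 0 and 1), 17 in-plane (x of atom 0)."""
    z0 = np.zeros((2, 3))
    z0[0, 2] = 1.0
    z1 = np.zeros((2, 3))
    z1[1, 2] = 1.0
    x0 = np.zeros((2, 3))
    x0[0, 0] = 1.0
    return [_mode(7, z1, OUT_OF_PLANE), _mode(8, z0, OUT_OF_PLANE),
            _mode(17, x0, IN_PLANE)]


class TestProjection:
    def test_basis_vector_projection(self, default_model):
        """Displacing along one orthonormal mode projects only onto it."""
        ref = default_model.reference_geometry
        geo = ref + 1.0 * default_model.modes[2].displacement
        p = projection_vector(geo, ref, default_model.modes)
        expected = np.zeros(len(default_model.modes))
        expected[2] = 1.0
        assert np.allclose(p, expected, atol=1e-10)

    def test_zero_distortion(self, default_model):
        ref = default_model.reference_geometry
        p = projection_vector(ref, ref, default_model.modes)
        assert np.allclose(p, 0.0, atol=1e-14)

    def test_linearity(self, default_model):
        rng = np.random.default_rng(0)
        ref = default_model.reference_geometry
        d = rng.normal(size=ref.shape)
        p1 = projection_vector(ref + d, ref, default_model.modes)
        p3 = projection_vector(ref + 3 * d, ref, default_model.modes)
        assert np.allclose(p3, 3 * p1, atol=1e-10)

    def test_parseval_identity(self):
        """A complete orthonormal mode set preserves the squared norm."""
        modes = synthetic_modes(n_atoms=4, seed=1)
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3))
        for _ in range(20):
            d = rng.normal(size=(4, 3))
            p = projection_vector(ref + d, ref, modes)
            assert np.sum(p ** 2) == pytest.approx(np.sum(d ** 2), abs=1e-10)

    def test_atom_mismatch_rejected(self, default_model):
        with pytest.raises(ValueError):
            projection_vector(np.zeros((3, 3)),
                              default_model.reference_geometry,
                              default_model.modes)


class TestPhaseAlignment:
    def test_sign_flip_rule(self, abc_modes):
        # per-geometry projections for modes (7, 8, 17)
        p = np.array([[0.2, -0.3, 0.5]])
        out = th.align_out_of_plane_phase(p, abc_modes, reference_mode=8)
        assert np.allclose(out, [[-0.2, 0.3, 0.5]])

    def test_positive_phase_untouched(self, abc_modes):
        p = np.array([[0.2, 0.3, 0.5]])
        out = th.align_out_of_plane_phase(p, abc_modes, reference_mode=8)
        assert np.allclose(out, p)

    def test_idempotent(self, abc_modes):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(50, 3))
        once = th.align_out_of_plane_phase(p, abc_modes, reference_mode=8)
        twice = th.align_out_of_plane_phase(once, abc_modes, reference_mode=8)
        assert np.allclose(once, twice, atol=1e-14)

    def test_in_plane_invariant(self, abc_modes):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(50, 3))
        out = th.align_out_of_plane_phase(p, abc_modes, reference_mode=8)
        assert np.allclose(out[:, 2], p[:, 2])

    def test_in_plane_reference_rejected(self, abc_modes):
        with pytest.raises(ValueError, match="out-of-plane"):
            th.align_out_of_plane_phase(np.zeros((1, 3)), abc_modes,
                                        reference_mode=17)


class TestHopGeometryStats:
    def _hop_traj(self, model, q_hop, t=10.0):
        return scripted_trajectory(model, [(t, "S2", "S1")], t_max_fs=20.0,
                                   q_of_t=lambda _: q_hop)

    def test_hand_statistics(self, default_model):
        """Two hop geometries with in-plane projections 0.1 and 0.3 give
        mu = 0.2 and population sigma = 0.1."""
        mode_pos = 3  # in-plane
        trs = [self._hop_traj(default_model,
                              np.eye(6)[mode_pos]
                              * q_for_projection(default_model, mode_pos, v))
               for v in (0.1, 0.3)]
        st = th.hop_geometry_stats(trs, ("S2", "S1"), default_model.modes,
                                   default_model.reference_geometry)
        assert st.n_hops == 2
        assert st.mu[mode_pos] == pytest.approx(0.2, abs=1e-10)
        assert st.sigma[mode_pos] == pytest.approx(0.1, abs=1e-10)

    def test_single_hop_zero_sigma(self, default_model):
        trs = [self._hop_traj(default_model, np.zeros(6))]
        st = th.hop_geometry_stats(trs, ("S2", "S1"), default_model.modes,
                                   default_model.reference_geometry)
        assert st.n_hops == 1
        assert np.allclose(st.sigma, 0.0)

    def test_alignment_before_statistics(self, default_model):
        """Out-of-plane projections +0.2/-0.2 align to mu = 0.2, sigma = 0."""
        mode_pos = 1  # out-of-plane N-H wag, index 2
        trs = [self._hop_traj(default_model,
                              np.eye(6)[mode_pos]
                              * q_for_projection(default_model, mode_pos, v))
               for v in (0.2, -0.2)]
        st = th.hop_geometry_stats(trs, ("S2", "S1"), default_model.modes,
                                   default_model.reference_geometry,
                                   reference_mode=2)
        assert st.mu[mode_pos] == pytest.approx(0.2, abs=1e-10)
        assert st.sigma[mode_pos] == pytest.approx(0.0, abs=1e-10)

    def test_no_matching_hops_flagged(self, default_model, fixture_ensemble):
        st = th.hop_geometry_stats(fixture_ensemble, ("T1", "T2"),
                                   default_model.modes,
                                   default_model.reference_geometry)
        assert st.empty and st.n_hops == 0


class TestCoherence:
    def test_fully_coherent_ensemble(self, default_model):
        """Identical trajectories: signed mean equals the trajectory value
        and unsigned mean its absolute value."""
        mode_pos = 3
        amp = q_for_projection(default_model, mode_pos, 0.3)
        omega = 2 * np.pi / 40.0  # period 40 fs

        def q_of_t(t):
            return np.eye(6)[mode_pos] * amp * np.sin(omega * t)

        trs = [scripted_trajectory(default_model, t_max_fs=100.0,
                                   q_of_t=q_of_t) for _ in range(5)]
        grid = np.arange(0.0, 101.0, 1.0)
        cs = th.coherence_series(trs, default_model.modes,
                                 default_model.reference_geometry, grid)
        expected = 0.3 * np.sin(omega * grid)
        assert np.allclose(cs.signed_mean[:, mode_pos], expected, atol=1e-8)
        assert np.allclose(cs.unsigned_mean[:, mode_pos], np.abs(expected),
                           atol=1e-8)

    def test_dephased_ensemble_signed_collapses(self, default_model):
        mode_pos = 3
        amp = q_for_projection(default_model, mode_pos, 0.3)
        omega = 2 * np.pi / 40.0
        rng = np.random.default_rng(5)
        trs = []
        for _ in range(1000):
            phi = rng.uniform(0, 2 * np.pi)
            trs.append(scripted_trajectory(
                default_model, t_max_fs=40.0, dt_fs=2.0,
                q_of_t=lambda t, phi=phi: np.eye(6)[mode_pos] * amp
                * np.sin(omega * t + phi)))
        grid = np.arange(0.0, 41.0, 2.0)
        cs = th.coherence_series(trs, default_model.modes,
                                 default_model.reference_geometry, grid)
        frac = (np.abs(cs.signed_mean[:, mode_pos])
                < 0.1 * cs.unsigned_mean[:, mode_pos])
        assert frac.mean() > 0.8

    def test_triangle_inequality(self, default_model):
        rng = np.random.default_rng(6)
        trs = [scripted_trajectory(
            default_model, t_max_fs=20.0, dt_fs=2.0,
            q_of_t=lambda t, r=rng.normal(size=6): r * np.sin(t / 3.0))
            for _ in range(20)]
        grid = np.arange(0.0, 21.0, 2.0)
        cs = th.coherence_series(trs, default_model.modes,
                                 default_model.reference_geometry, grid)
        assert np.all(cs.unsigned_mean >= np.abs(cs.signed_mean) - 1e-12)


class TestBondLengths:
    def test_static_distance(self, diatomic_model):
        tr = scripted_trajectory(diatomic_model, t_max_fs=10.0, initial="S0")
        bs = th.bond_length_series([tr], ("N1", "H2"))
        assert np.allclose(bs.all_values, 1.0)
        assert bs.summary["sd"] == 0.0

    def test_two_frame_hand_values(self, diatomic_model):
        dq = q_for_projection(diatomic_model, 0, 0.2)

        def q_of_t(t):
            return np.array([dq if t > 0 else 0.0, 0.0])

        tr = scripted_trajectory(diatomic_model, t_max_fs=1.0, dt_fs=1.0,
                                 initial="S0", q_of_t=q_of_t)
        bs = th.bond_length_series([tr], ("N1", "H2"))
        assert bs.all_values == pytest.approx([1.0, 1.2])
        assert bs.summary["mean"] == pytest.approx(1.1)
        assert bs.summary["max"] == pytest.approx(1.2)

    def test_rigid_translation_invariance(self, diatomic_model):
        """Displacing along the translation mode leaves the bond length
        unchanged."""
        dq = q_for_projection(diatomic_model, 1, 5.0)
        tr = scripted_trajectory(diatomic_model, t_max_fs=4.0, dt_fs=1.0,
                                 initial="S0",
                                 q_of_t=lambda t: np.array([0.0, t * dq]))
        bs = th.bond_length_series([tr], ("N1", "H2"))
        assert np.allclose(bs.all_values, 1.0, atol=1e-10)

    def test_unknown_atom_label_rejected(self, diatomic_model):
        tr = scripted_trajectory(diatomic_model, t_max_fs=5.0, initial="S0")
        with pytest.raises(ValueError, match="label"):
            th.bond_length_series([tr], ("N1", "X9"))

    def test_default_reference_bond_lengths(self, default_model):
        """The Franck-Condon skeleton has r(N-H) = 1.03 A and
        r(S-H) close to 2.8 A."""
        tr = scripted_trajectory(default_model, t_max_fs=2.0)
        nh = th.bond_length_series([tr], ("N1", "H8"))
        sh = th.bond_length_series([tr], ("S7", "H8"))
        assert nh.summary["mean"] == pytest.approx(1.03, abs=1e-9)
        assert sh.summary["mean"] == pytest.approx(2.8, abs=0.1)


class TestMecpComparison:
    def test_mecp_equals_mean_hop_geometry(self, default_model):
        mode_pos = 3
        q = np.eye(6)[mode_pos] * q_for_projection(default_model, mode_pos, 0.25)
        tr = scripted_trajectory(default_model, [(10.0, "S2", "S1")],
                                 t_max_fs=20.0, q_of_t=lambda _: q)
        st = th.hop_geometry_stats([tr], ("S2", "S1"), default_model.modes,
                                   default_model.reference_geometry)
        mecp = default_model.cartesian_geometry(q)
        table = th.compare_to_mecp(st, mecp, default_model.reference_geometry,
                                   default_model.modes)
        in_plane = table[table.character == "in_plane"]
        assert np.allclose(in_plane.abs_diff.to_numpy(), 0.0, atol=1e-10)

    def test_out_of_plane_band_rule(self, default_model):
        st = th.HopGeometryStats(
            transition=("S1", "T2"),
            mode_indices=[m.index for m in default_model.modes],
            mu=np.array([0.0, 0.1, 0.0, 0.0, 0.0, 0.0]),
            sigma=np.array([0.0, 0.1, 0.0, 0.0, 0.0, 0.0]),
            n_hops=5)
        mecp = (default_model.reference_geometry
                + 0.5 * default_model.modes[1].displacement)
        table = th.compare_to_mecp(st, mecp,
                                   default_model.reference_geometry,
                                   default_model.modes)
        assert table.loc[2, "p_mecp"] == pytest.approx(0.5, abs=1e-10)
        assert table.loc[2, "within_band"] == False  # |0.5| > 0.1 + 2*0.1

    def test_reference_mecp_projects_to_zero(self, default_model):
        st = th.HopGeometryStats(
            transition=("S2", "S1"),
            mode_indices=[m.index for m in default_model.modes],
            mu=np.zeros(6), sigma=np.zeros(6), n_hops=1)
        table = th.compare_to_mecp(st, default_model.reference_geometry,
                                   default_model.reference_geometry,
                                   default_model.modes)
        assert np.allclose(table.p_mecp.to_numpy(), 0.0, atol=1e-14)
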