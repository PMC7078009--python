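import numpy as np
import pytest

import thiohop as th
from thiohop import units
from thiohop.vibronic import IN_PLANE, OUT_OF_PLANE, NormalMode


@pytest.fixture(scope="session")
def default_model():
    return th.default_model()


@pytest.fixture(scope="session")
def fixture_ensemble(default_model):
    """The hand-checkable 3-trajectory scripted ensemble."""
    from thiohop.fixtures import three_trajectory_ensemble
    return three_trajectory_ensemble(default_model)


def two_state_model(gap_ev=1.0, lam_ev=0.0, soc_ev=0.0, freq_cm1=1000.0,
                    kappa_ev=(0.0, 0.0), multiplicities=(1, 1)):
    """Minimal 2-state 1-mode model for closed-form checks."""
    cfg = {
        "states": [{"label": "A", "multiplicity": multiplicities[0]},
                   {"label": "B", "multiplicity": multiplicities[1]}],
        "energies_eV": {"A": 0.0, "B": gap_ev},
        "modes": [{"freq_cm1": freq_cm1, "character": IN_PLANE,
                   "reduced_mass_amu": 1.0}],
        "kappa_eV": {"A": [kappa_ev[0]], "B": [kappa_ev[1]]},
    }
    if lam_ev:
        cfg["lambda_eV"] = {"A|B": [lam_ev]}
    if soc_ev:
        cfg["soc_eV"] = {"A|B": soc_ev}
    return th.build_lvc_model(cfg)


@pytest.fixture
def diatomic_model():
    """Two-atom model with unit-Cartesian modes for bond-length checks.

    Mode 1 stretches the bond (moves only the H atom along x); mode 2
    translates both atoms rigidly along x.
    """
    stretch = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    translate = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]) / np.sqrt(2)
    cfg = {
        "states": [{"label": "S0", "multiplicity": 1},
                   {"label": "S1", "multiplicity": 1}],
        "energies_eV": {"S0": 0.0, "S1": 2.0},
        "modes": [
            {"index": 1, "freq_cm1": 2000.0, "character": IN_PLANE,
             "reduced_mass_amu": 1.0, "displacement": stretch.tolist()},
            {"index": 2, "freq_cm1": 100.0, "character": IN_PLANE,
             "reduced_mass_amu": 15.0, "displacement": translate.tolist()},
        ],
        "reference_geometry": {
            "symbols": ["N", "H"],
            "coords_angstrom": [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
        },
    }
    return th.build_lvc_model(cfg)


def q_for_projection(model, mode_pos, p_angstrom):
    """Dimensionless coordinate giving a Cartesian projection p (Angstrom)
    along mode ``mode_pos`` of ``model``."""
    m = model.modes[mode_pos]
    return p_angstrom / (m.cartesian_amplitude * units.ANGSTROM_PER_BOHR)


def synthetic_modes(n_atoms=4, seed=0):
    """A complete orthonormal set of 3*n_atoms synthetic modes, half of them
    labeled out-of-plane."""
    rng = np.random.default_rng(seed)
    dim = 3 * n_atoms
    basis, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    modes = []
    for k in range(dim):
        modes.append(NormalMode(
            index=k + 1, frequency=0.005,
            displacement=basis[:, k].reshape(n_atoms, 3),
            character=OUT_OF_PLANE if k % 2 else IN_PLANE,
            reduced_mass=1.0 * units.AMU_TO_AU))
    return modes
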