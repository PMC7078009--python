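"""Default 2-thiopyridone-like model and run configuration.

The default model is a synthetic stand-in for ab initio surfaces: five
electronic states (S0, S1, S2, T1, T2) with the Franck-Condon vertical
excitation energies of the thiopyridone system, six harmonic normal modes
of a planar 12-atom molecule, and illustrative vibronic/spin-orbit
couplings chosen to yield the qualitative photophysics of thionated
heteroaromatics: ultrafast S2 -> S1 internal conversion driven by in-plane
modes, slower intersystem crossing into the triplet manifold through
constant spin-orbit couplings, and a minority S1 -> S0 channel.

The coupling magnitudes are not fitted to any reference data; they are a
declared model choice (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .vibronic import IN_PLANE, OUT_OF_PLANE, build_lvc_model


def reference_geometry():
    """Planar 2-thiopyridone-like skeleton (Angstrom), 12 atoms.

    Six-membered ring (N + 5C) as a regular hexagon of side 1.39 A, sulfur
    on the ring carbon adjacent to nitrogen, one H on N and one on each of
    the four remaining ring carbons.  The molecule lies in the z = 0 plane.
    """
    R = 1.39
    angles = np.deg2rad([90, 30, -30, -90, -150, 150])
    ring = np.stack([R * np.cos(angles), R * np.sin(angles), np.zeros(6)], axis=1)
    symbols = ["N", "C", "C", "C", "C", "C"]
    coords = list(ring)

    def radial(i, dist):
        u = ring[i] / np.linalg.norm(ring[i])
        return ring[i] + dist * u

    coords.append(radial(1, 1.68))   # S on C2
    symbols.append("S")
    coords.append(radial(0, 1.03))   # H on N
    symbols.append("H")
    for i in (2, 3, 4, 5):           # ring C-H
        coords.append(radial(i, 1.08))
        symbols.append("H")
    return symbols, np.asarray(coords)


def _orthonormalize(raw, masks):
    """Gram-Schmidt within each Cartesian-component mask group."""
    out = []
    for v, mask in zip(raw, masks):
        v = v.copy()
        for u, m2 in zip(out, masks):
            if m2 == mask:
                v -= np.sum(v * u) * u
        v /= np.linalg.norm(v)
        out.append(v)
    return out


def default_mode_set():
    """Six synthetic normal modes of the reference skeleton.

    Two out-of-plane modes (ring torsion; N-H wag, the phase-alignment
    reference) and four in-plane modes (ring breathing; N-H rock; ring
    stretch; N-H stretch).  Displacement patterns are orthonormalized
    within each symmetry block, so in-plane and out-of-plane vectors are
    mutually orthogonal by construction.
    """
    symbols, geo = reference_geometry()
    nat = len(symbols)
    iN, iS, iHN = 0, 6, 7

    def blank():
        return np.zeros((nat, 3))

    raw = []
    # mode 1: ring torsion (out of plane, alternating z on ring atoms)
    v = blank()
    for i in range(6):
        v[i, 2] = (-1) ** i
    v[iHN, 2] = -0.4
    raw.append(v)
    # mode 2: N-H wag (out of plane, H_N dominated) -- alignment reference
    v = blank()
    v[iHN, 2] = 1.0
    v[iN, 2] = -0.25
    raw.append(v)
    # mode 3: ring breathing (in plane, radial)
    v = blank()
    for i in range(6):
        v[i, :2] = geo[i, :2] / np.linalg.norm(geo[i, :2])
    v[iS, :2] = 0.3 * geo[iS, :2] / np.linalg.norm(geo[iS, :2])
    raw.append(v)
    # mode 4: N-H in-plane rock (H_N tangential)
    v = blank()
    u = geo[iHN, :2] / np.linalg.norm(geo[iHN, :2])
    v[iHN, :2] = np.array([-u[1], u[0]])
    v[iN, :2] = -0.15 * np.array([-u[1], u[0]])
    raw.append(v)
    # mode 5: ring stretch (in plane, tangential alternating)
    v = blank()
    for i in range(6):
        u = geo[i, :2] / np.linalg.norm(geo[i, :2])
        v[i, :2] = (-1) ** i * np.array([-u[1], u[0]])
    raw.append(v)
    # mode 6: N-H stretch (H_N radial)
    v = blank()
    v[iHN, :2] = geo[iHN, :2] / np.linalg.norm(geo[iHN, :2])
    v[iN, :2] = -0.1 * geo[iN, :2] / np.linalg.norm(geo[iN, :2])
    raw.append(v)

    characters = [OUT_OF_PLANE, OUT_OF_PLANE, IN_PLANE, IN_PLANE, IN_PLANE, IN_PLANE]
    vecs = _orthonormalize(raw, characters)

    freqs_cm1 = [420.0, 560.0, 980.0, 1260.0, 1560.0, 3280.0]
    masses_amu = [5.0, 1.2, 6.5, 1.15, 5.5, 1.05]
    modes = []
    for k in range(6):
        modes.append(dict(
            index=k + 1,
            freq_cm1=freqs_cm1[k],
            character=characters[k],
            reduced_mass_amu=masses_amu[k],
            displacement=vecs[k].tolist(),
        ))
    return modes


def default_model_config():
    """Full structured parameter set for the default model."""
    symbols, geo = reference_geometry()
    config = {
        "states": [
            {"label": "S0", "multiplicity": 1},
            {"label": "S1", "multiplicity": 1},
            {"label": "S2", "multiplicity": 1},
            {"label": "T1", "multiplicity": 3},
            {"label": "T2", "multiplicity": 3},
        ],
        # Franck-Condon vertical excitation energies (eV); the CASPT2-
        # corrected values are carried as metadata only.
        "energies_eV": {"S0": 0.0, "S1": 3.16, "S2": 3.82, "T1": 2.64, "T2": 2.90},
        "metadata": {
            "character": {"S1": "(n,pi*)", "S2": "(pi,pi*)",
                          "T1": "(pi,pi*)", "T2": "(n,pi*)"},
            "energies_pt2_eV": {"S1": 3.34, "S2": 3.64, "T1": 2.92, "T2": 3.31},
        },
        "modes": default_mode_set(),
        # Intrastate gradients (eV per dimensionless q).  Out-of-plane
        # entries vanish for the planar reference; in-plane entries displace
        # the excited-state minima away from the Franck-Condon point.
        "kappa_eV": {
            "S1": [0.0, 0.0, 0.06, 0.05, 0.08, -0.04],
            "S2": [0.0, 0.0, -0.09, 0.07, -0.12, -0.03],
            "T1": [0.0, 0.0, -0.07, 0.04, -0.10, -0.03],
            "T2": [0.0, 0.0, 0.05, 0.06, 0.07, -0.04],
        },
        # Interstate vibronic couplings within each multiplicity (eV per q).
        "lambda_eV": {
            "S1|S2": [0.0, 0.0, 0.03, 0.10, 0.08, 0.0],
            "S0|S1": [0.02, 0.02, 0.01, 0.02, 0.0, 0.0],
            "T1|T2": [0.03, 0.03, 0.01, 0.03, 0.02, 0.0],
        },
        # Constant effective spin-orbit couplings (eV): the scalar per
        # singlet-triplet pair is the root-sum-square over the three
        # sublevels, heavy-atom (sulfur) scale.
        "soc_eV": {
            "S1|T2": 0.040,
            "S2|T2": 0.024,
            "S1|T1": 0.016,
            "S2|T1": 0.012,
            "S0|T1": 0.008,
            "S0|T2": 0.006,
        },
        "triplet_components": 1,
        "reference_geometry": {
            "symbols": symbols,
            "coords_angstrom": geo.tolist(),
        },
    }
    return config


def default_model():
    """The default five-state six-mode model, ready to propagate."""
    return build_lvc_model(default_model_config())


def default_run_config():
    """Default end-to-end pipeline configuration (structured dict)."""
    return {
        "model": default_model_config(),
        "sampling": {"n_traj": 100, "seed": 2020, "initial_state": "S2"},
        "propagation": {
            "dt_fs": 0.5,
            "substeps": 100,
            "decoherence_C_hartree": 0.1,
            "t_max_fs": 1000.0,
            "frustrated_policy": "continue",
        },
        "analysis": {
            "grid_fs": {"start": 0.0, "stop": 1000.0, "n": 201},
            "manifolds": {"singlets": ["S0", "S1", "S2"], "triplets": ["T1", "T2"]},
            "bond_pairs": [["N1", "H8"], ["S7", "H8"]],
            "reference_mode_index": 2,
            "hop_report_threshold": 10,
        },
    }
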