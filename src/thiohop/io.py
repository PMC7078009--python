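"""File formats: Molden-style frequency files, multi-frame XYZ, config.

The Molden reader consumes the ``[FR-COORD]`` (bohr), ``[FREQ]`` (cm^-1)
and ``[FR-NORM-COORD]`` blocks of a frequency calculation and returns the
reference geometry in Angstrom plus unit-normalized NormalMode records.
Multi-frame XYZ uses Angstrom with the time (fs) and active state on the
comment line.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from . import units
from .vibronic import IN_PLANE, NormalMode


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Molden frequency files
# ---------------------------------------------------------------------------

def read_normal_modes(path, characters=None, reduced_masses_amu=None,
                      log=None):
    """Read a Molden-style frequency file.

    Returns ``(symbols, reference_geometry_angstrom, modes)``.  Displacement
    vectors are renormalized to unit Euclidean norm (factors logged via the
    ``log`` callable when given); frequencies are converted cm^-1 -> a.u.
    ``characters``/``reduced_masses_amu`` optionally attach per-mode
    metadata the file format does not carry.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    blocks = {}
    current = None
    for ln in lines:
        s = ln.strip()
        if s.startswith("["):
            current = s.split("]")[0].strip("[").upper()
            blocks[current] = []
        elif current is not None and s:
            blocks[current].append(s)

    for required in ("FR-COORD", "FREQ", "FR-NORM-COORD"):
        if required not in blocks:
            raise ParseError(f"missing [{required}] block in {path}")

    symbols, coords = [], []
    for s in blocks["FR-COORD"]:
        parts = s.split()
        if len(parts) != 4:
            raise ParseError(f"malformed [FR-COORD] line: {s!r}")
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:]])
    coords = np.asarray(coords) * units.ANGSTROM_PER_BOHR
    nat = len(symbols)

    freqs = [float(s.split()[0]) for s in blocks["FREQ"]]

    vib_lines = blocks["FR-NORM-COORD"]
    modes_raw = []
    i = 0
    while i < len(vib_lines):
        head = vib_lines[i].lower()
        if not head.startswith("vibration"):
            raise ParseError(f"expected 'vibration' header, got {vib_lines[i]!r}")
        vec = []
        i += 1
        while i < len(vib_lines) and not vib_lines[i].lower().startswith("vibration"):
            vec.append([float(x) for x in vib_lines[i].split()])
            i += 1
        if len(vec) != nat:
            raise ParseError(
                f"[FR-NORM-COORD] vibration has {len(vec)} atoms, "
                f"[FR-COORD] has {nat}")
        modes_raw.append(np.asarray(vec))

    if len(modes_raw) != len(freqs):
        raise ParseError(f"{len(freqs)} frequencies but {len(modes_raw)} "
                         "displacement blocks")

    modes = []
    for k, (f_cm1, vec) in enumerate(zip(freqs, modes_raw)):
        nrm = np.linalg.norm(vec)
        if nrm == 0:
            raise ParseError(f"zero-norm displacement vector for mode {k + 1}")
        if log is not None and abs(nrm - 1.0) > 1e-10:
            log(f"mode {k + 1}: renormalized displacement (norm was {nrm:.6f})")
        modes.append(NormalMode(
            index=k + 1,
            frequency=f_cm1 * units.HARTREE_PER_CM1,
            displacement=vec / nrm,
            character=(characters[k] if characters else IN_PLANE),
            reduced_mass=(reduced_masses_amu[k] if reduced_masses_amu else 1.0)
            * units.AMU_TO_AU,
        ))
    return symbols, coords, modes


def write_normal_modes(path, symbols, reference_angstrom, modes):
    """Write a Molden-style frequency file (inverse of read_normal_modes)."""
    ref_bohr = np.asarray(reference_angstrom) * units.BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write("[Molden Format]\n[FREQ]\n")
        for m in modes:
            fh.write(f"{m.frequency * units.CM1_PER_HARTREE:.6f}\n")
        fh.write("[FR-COORD]\n")
        for s, xyz in zip(symbols, ref_bohr):
            fh.write(f"{s} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
        fh.write("[FR-NORM-COORD]\n")
        for k, m in enumerate(modes):
            fh.write(f"vibration {k + 1}\n")
            for row in m.displacement:
                fh.write(f" {row[0]:.10f} {row[1]:.10f} {row[2]:.10f}\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, symbols, frames, comments=None, mode="w"):
    """Write a (multi-frame) XYZ file; coordinates in Angstrom."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, mode) as fh:
        for i, geo in enumerate(frames):
            fh.write(f"{len(symbols)}\n")
            fh.write((comments[i] if comments else "") + "\n")
            for s, xyz in zip(symbols, geo):
                fh.write(f"{s} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def read_xyz(path):
    """Read a (multi-frame) XYZ file -> (symbols, frames, comments)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, comments = [], []
    symbols = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"expected atom count at line {i + 1}") from exc
        comments.append(lines[i + 1])
        syms, geo = [], []
        for ln in lines[i + 2:i + 2 + nat]:
            parts = ln.split()
            syms.append(parts[0])
            geo.append([float(x) for x in parts[1:4]])
        if symbols is None:
            symbols = syms
        elif syms != symbols:
            raise ParseError("inconsistent atom lists between XYZ frames")
        frames.append(geo)
        i += 2 + nat
    return symbols, np.asarray(frames), comments


def export_trajectory_xyz(path, trajectory, stride=1):
    """Multi-frame XYZ export of a trajectory (comment: time and state)."""
    model = trajectory.model
    if model.reference_geometry is None or model.atom_symbols is None:
        raise ValueError("model carries no Cartesian reference geometry")
    idx = range(0, len(trajectory), stride)
    geos = [model.cartesian_geometry(trajectory.q[i]) for i in idx]
    comments = [f"t= {trajectory.times[i]:.2f} fs  active= "
                f"{trajectory.mch_labels_series[i]}" for i in idx]
    write_xyz(path, model.atom_symbols, np.asarray(geos), comments)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"model", "sampling", "propagation", "analysis"}
_SAMPLING_KEYS = {"n_traj", "seed", "initial_state"}
_PROP_KEYS = {"dt_fs", "substeps", "decoherence_C_hartree", "t_max_fs",
              "frustrated_policy", "frozen_nuclei"}
_ANALYSIS_KEYS = {"grid_fs", "manifolds", "bond_pairs",
                  "reference_mode_index", "hop_report_threshold"}


def validate_run_config(config: dict) -> dict:
    """Structural validation of a pipeline configuration; rejects unknown
    keys so typos fail before any compute."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ParseError(f"unknown top-level config keys: {sorted(unknown)}")
    for section, allowed in (("sampling", _SAMPLING_KEYS),
                             ("propagation", _PROP_KEYS),
                             ("analysis", _ANALYSIS_KEYS)):
        extra = set(config.get(section, {})) - allowed
        if extra:
            raise ParseError(f"unknown keys in {section!r}: {sorted(extra)}")
    if "model" not in config:
        raise ParseError("config is missing the model section")
    return config


def load_run_config(path) -> dict:
    with open(path) as fh:
        return validate_run_config(yaml.safe_load(fh))


def save_run_config(path, config: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration (provenance stamp)."""
    blob = json.dumps(config, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trajectory bundles
# ---------------------------------------------------------------------------

def save_trajectory_h5(path, trajectory):
    """One HDF5 bundle per trajectory (arrays + hop table + provenance)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dt_fs"] = trajectory.params.dt_fs
        h5.attrs["substeps"] = trajectory.params.substeps
        h5.attrs["decoherence_C_hartree"] = trajectory.params.decoherence_C
        h5.attrs["rng_seed"] = trajectory.params.rng_seed
        h5.create_dataset("t_fs", data=trajectory.times)
        h5.create_dataset("q", data=trajectory.q)
        h5.create_dataset("p", data=trajectory.p)
        h5.create_dataset("diag_energies", data=trajectory.diag_energies)
        h5.create_dataset("mch_energies", data=trajectory.mch_energies)
        h5.create_dataset("pop_diag", data=trajectory.amplitude_populations("diag"))
        h5.create_dataset("pop_mch", data=trajectory.amplitude_populations("mch"))
        h5.create_dataset("active", data=trajectory.active)
        hop_rows = [(h.t, h.from_state, h.to_state, h.from_diag, h.to_diag,
                     int(h.frustrated), h.potential_gap)
                    for h in trajectory.hops]
        h5.create_dataset("hops", data=np.array(
            [(t, f.encode(), to.encode(), fd, td, fr, gap)
             for t, f, to, fd, td, fr, gap in hop_rows],
            dtype=[("t_fs", "f8"), ("from", "S16"), ("to", "S16"),
                   ("from_diag", "i4"), ("to_diag", "i4"),
                   ("frustrated", "i4"), ("gap_hartree", "f8")]))
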