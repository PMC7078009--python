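"""Analytic linear vibronic coupling (LVC) model with spin-orbit coupling.

The electronic-structure stand-in used throughout the package: a multi-state
harmonic Hamiltonian over dimensionless normal-mode coordinates q,

    H_nn(q) = eps_n + sum_i (w_i/2) q_i^2 + sum_i kappa_i^(n) q_i
    H_nm(q) = sum_i lambda_i^(nm) q_i          (same spin multiplicity)
    H_nm    = V_SO^(nm)                        (singlet-triplet pairs)

Diagonalizing the spin-free blocks gives the MCH (molecular Coulomb
Hamiltonian) states of pure multiplicity; diagonalizing the full matrix
including the spin-orbit blocks gives the spin-mixed "diagonal" states in
which trajectories are propagated.

All quantities are in atomic units internally (hbar = 1); constructors
accept eV and cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units


class ModelValidationError(ValueError):
    """Raised when a model specification violates a structural invariant."""


IN_PLANE = "in_plane"
OUT_OF_PLANE = "out_of_plane"


@dataclass
class NormalMode:
    """A harmonic normal mode.

    Parameters
    ----------
    index : int
        Mode label (1-based by convention, following quantum-chemistry
        frequency outputs).
    frequency : float
        Harmonic frequency in atomic units (Hartree, since hbar = 1).
    displacement : (natom, 3) ndarray
        Mass-unweighted Cartesian displacement pattern, unit Euclidean norm.
    character : str
        ``"in_plane"`` or ``"out_of_plane"``.
    reduced_mass : float
        Reduced mass in atomic units (electron masses).
    """

    index: int
    frequency: float
    displacement: np.ndarray
    character: str = IN_PLANE
    reduced_mass: float = 1.0 * units.AMU_TO_AU

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.frequency <= 0:
            raise ModelValidationError(
                f"mode {self.index}: frequency must be positive, got {self.frequency}"
            )
        nrm = np.linalg.norm(self.displacement)
        if nrm == 0:
            raise ModelValidationError(f"mode {self.index}: zero-norm displacement vector")
        if abs(nrm - 1.0) > 1e-8:
            self.displacement = self.displacement / nrm
        if self.character not in (IN_PLANE, OUT_OF_PLANE):
            raise ModelValidationError(
                f"mode {self.index}: unknown character {self.character!r}"
            )

    @property
    def cartesian_amplitude(self) -> float:
        """Length scale sqrt(1/(mu*omega)) in bohr converting the
        dimensionless coordinate q to a Cartesian displacement."""
        return 1.0 / np.sqrt(self.reduced_mass * self.frequency)


@dataclass
class StateLabel:
    label: str
    multiplicity: int  # 1 = singlet, 3 = triplet

    def __str__(self):
        return self.label


@dataclass
class ElectronicStructure:
    """Electronic structure at one geometry.

    ``transform`` maps MCH states to diagonal (spin-mixed) states:
    column k holds the MCH-basis expansion of diagonal state k.
    """

    mch_energies: np.ndarray          # per expanded state, MCH eigenvalues
    soc_matrix: np.ndarray            # full Hamiltonian in the diabatic basis
    diag_energies: np.ndarray         # ascending eigenvalues incl. SOC
    transform: np.ndarray             # MCH -> diagonal unitary
    gradients: np.ndarray             # (nstate_diag, nmode) Hellmann-Feynman
    eigenvectors: np.ndarray          # diabatic -> diagonal unitary
    mch_vectors: np.ndarray           # diabatic -> MCH unitary (block diagonal)
    mch_labels: list = field(default_factory=list)

    def mch_parent(self, k: int) -> int:
        """Index of the MCH state dominating diagonal state k."""
        return int(np.argmax(np.abs(self.transform[:, k]) ** 2))


def _fix_phases(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component real and positive."""
    U = U.copy()
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        z = U[j, k]
        if z != 0:
            U[:, k] *= np.conj(z) / abs(z)
    return U


def align_phases(U: np.ndarray, U_prev: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Phase-track eigenvectors against a previous geometry.

    Each column of ``U`` is multiplied by the unit phase making its overlap
    with the corresponding column of ``U_prev`` real and positive; columns
    with negligible overlap keep their deterministic phase.
    """
    U = U.copy()
    for k in range(U.shape[1]):
        o = np.vdot(U_prev[:, k], U[:, k])
        if abs(o) > tol:
            U[:, k] *= np.conj(o) / abs(o)
    return U


class VibronicModel:
    """Multi-state LVC Hamiltonian over harmonic modes with constant SOC.

    Parameters (all in atomic units):

    states : list of StateLabel
    energies : (nbase,) vertical energies eps_n at the origin
    kappa : (nbase, nmode) intrastate gradients
    lam : (nbase, nbase, nmode) interstate couplings, symmetric in the state
        indices and zero across multiplicities
    soc : (nbase, nbase) complex, Hermitian, zero within a multiplicity
    modes : list of NormalMode
    triplet_components : 1 (scalar effective SOC, default) or 3 (degenerate
        sublevels sharing the SOC constant)
    reference_geometry : optional (natom, 3) Cartesian reference in Angstrom
    atom_symbols : optional element symbols matching the reference geometry
    """

    def __init__(self, states, energies, kappa, lam, soc, modes,
                 triplet_components=1, reference_geometry=None,
                 atom_symbols=None, metadata=None):
        self.states = list(states)
        self.energies = np.asarray(energies, dtype=float)
        self.kappa = np.asarray(kappa, dtype=float)
        self.lam = np.asarray(lam, dtype=float)
        self.soc = np.asarray(soc, dtype=complex)
        self.modes = list(modes)
        self.triplet_components = int(triplet_components)
        self.reference_geometry = (
            None if reference_geometry is None
            else np.asarray(reference_geometry, dtype=float)
        )
        self.atom_symbols = atom_symbols
        self.metadata = dict(metadata or {})
        self._validate()
        self._build_expansion()

    # -- validation ------------------------------------------------------
    def _validate(self):
        nb, nm = len(self.states), len(self.modes)
        if nb < 2:
            raise ModelValidationError("at least two electronic states required")
        if nm < 1:
            raise ModelValidationError("at least one mode required")
        if not np.all(np.isfinite(self.energies)):
            raise ModelValidationError("non-finite state energies")
        if self.energies.shape != (nb,):
            raise ModelValidationError("energies shape mismatch")
        if self.kappa.shape != (nb, nm):
            raise ModelValidationError("kappa must be (nstate, nmode)")
        if self.lam.shape != (nb, nb, nm):
            raise ModelValidationError("lambda must be (nstate, nstate, nmode)")
        if self.soc.shape != (nb, nb):
            raise ModelValidationError("soc must be (nstate, nstate)")
        if not np.allclose(self.lam, np.transpose(self.lam, (1, 0, 2)), atol=1e-12):
            raise ModelValidationError("lambda couplings must be symmetric in state indices")
        if not np.allclose(self.soc, self.soc.conj().T, atol=1e-12):
            raise ModelValidationError("SOC matrix must be Hermitian")
        for a in range(nb):
            if abs(self.soc[a, a]) > 0:
                raise ModelValidationError("diagonal SOC entries must vanish")
            for b in range(nb):
                ma, mb = self.states[a].multiplicity, self.states[b].multiplicity
                if ma == mb and a != b and abs(self.soc[a, b]) > 0:
                    raise ModelValidationError(
                        f"SOC between same-multiplicity states "
                        f"{self.states[a]}/{self.states[b]} is forbidden"
                    )
                if ma != mb and np.any(np.abs(self.lam[a, b]) > 0):
                    raise ModelValidationError(
                        f"vibronic coupling across multiplicities "
                        f"{self.states[a]}/{self.states[b]} is forbidden"
                    )
        if self.triplet_components not in (1, 3):
            raise ModelValidationError("triplet_components must be 1 or 3")

    def _build_expansion(self):
        """Map base states to (possibly replicated) Hamiltonian rows and
        precompute the expanded coupling tensors used at every geometry."""
        self._expanded_base = []   # base-state index per Hamiltonian row
        self._expanded_labels = []
        comp = []                  # sublevel component index per row
        for i, s in enumerate(self.states):
            ncomp = self.triplet_components if s.multiplicity == 3 else 1
            for m in range(ncomp):
                self._expanded_base.append(i)
                comp.append(m)
                suffix = f"(ms{m - 1:+d})" if ncomp == 3 else ""
                self._expanded_labels.append(s.label + suffix)
        self._expanded_base = np.asarray(self._expanded_base)
        self._comp = np.asarray(comp)

        base = self._expanded_base
        n = len(base)
        mult = np.array([self.states[b].multiplicity for b in base])
        same_mult = mult[:, None] == mult[None, :]
        same_comp = self._comp[:, None] == self._comp[None, :]
        offdiag = ~np.eye(n, dtype=bool)

        self._energies_x = self.energies[base]
        self._kappa_x = self.kappa[base]
        lam_x = self.lam[np.ix_(base, base)]            # (n, n, nmode)
        lam_mask = (same_mult & same_comp & offdiag)
        self._lam_x = lam_x * lam_mask[:, :, None]
        self._soc_x = self.soc[np.ix_(base, base)] * (~same_mult)
        self._row_mult = mult

    # -- basic queries ---------------------------------------------------
    @property
    def nmodes(self) -> int:
        return len(self.modes)

    @property
    def nstates(self) -> int:
        """Number of rows of the Hamiltonian (sublevels expanded)."""
        return len(self._expanded_base)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.modes])

    @property
    def state_labels(self):
        return [s.label for s in self.states]

    @property
    def expanded_labels(self):
        return list(self._expanded_labels)

    def state_index(self, label: str) -> int:
        """Hamiltonian row of the first component carrying ``label``."""
        for k, b in enumerate(self._expanded_base):
            if self.states[b].label == label:
                return k
        raise KeyError(label)

    def base_label(self, row: int) -> str:
        return self.states[self._expanded_base[row]].label

    def multiplicity_of_row(self, row: int) -> int:
        return self.states[self._expanded_base[row]].multiplicity

    # -- Hamiltonian assembly -------------------------------------------
    def potential_matrix(self, q: np.ndarray) -> np.ndarray:
        """Full diabatic-basis Hamiltonian (incl. SOC) at coordinates q."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self.nmodes,) or not np.all(np.isfinite(q)):
            raise ValueError("q must hold one finite value per mode")
        w = self.frequencies
        vho = 0.5 * np.sum(w * q * q)
        H = (self._lam_x @ q).astype(complex)
        H += self._soc_x
        np.fill_diagonal(H, self._energies_x + vho + self._kappa_x @ q)
        return H

    def spinfree_matrix(self, q: np.ndarray) -> np.ndarray:
        """Hamiltonian with the SOC blocks zeroed (block diagonal in spin)."""
        H = self.potential_matrix(q)
        return H - self._soc_x

    def _dH_dq(self, q: np.ndarray) -> np.ndarray:
        """Derivative tensor (nmode, n, n) of the full Hamiltonian (SOC is
        constant and drops out)."""
        dH = np.transpose(self._lam_x, (2, 0, 1)).copy()
        diag = self.frequencies[:, None] * q[:, None] + self._kappa_x.T  # (nmode, n)
        idx = np.arange(self.nstates)
        dH[:, idx, idx] += diag
        return dH

    # -- evaluation ------------------------------------------------------
    def evaluate(self, q, prev_eigenvectors=None) -> ElectronicStructure:
        """Diagonalize the model at coordinates ``q``.

        ``prev_eigenvectors`` (diabatic->diagonal unitary from the previous
        geometry) enables phase tracking for overlap-based propagation.
        """
        H = self.potential_matrix(q)
        evals, evecs = np.linalg.eigh(H)
        evecs = _fix_phases(evecs)
        if prev_eigenvectors is not None:
            evecs = align_phases(evecs, prev_eigenvectors)

        Hsf = self.spinfree_matrix(q)
        mch_evals, mch_vecs = np.linalg.eigh(Hsf)
        # reorder MCH states so state j stays attached to diabatic state j
        # (dominant-component assignment), keeping labels meaningful
        order = np.empty(self.nstates, dtype=int)
        taken = np.zeros(self.nstates, dtype=bool)
        for j in np.argsort(-np.max(np.abs(mch_vecs), axis=0)):
            cand = np.argsort(-np.abs(mch_vecs[:, j]))
            for c in cand:
                if not taken[c]:
                    order[c] = j
                    taken[c] = True
                    break
        mch_evals = mch_evals[order]
        mch_vecs = _fix_phases(mch_vecs[:, order])
        mch_labels = [self._expanded_labels[j] for j in range(self.nstates)]

        transform = mch_vecs.conj().T @ evecs
        # Hellmann-Feynman gradients of the diagonal surfaces
        dH = self._dH_dq(np.asarray(q, dtype=float))
        grads = np.real(np.einsum("ak,iab,bk->ki", evecs.conj(), dH, evecs))
        return ElectronicStructure(
            mch_energies=mch_evals,
            soc_matrix=H,
            diag_energies=evals,
            transform=transform,
            gradients=grads,
            eigenvectors=evecs,
            mch_vectors=mch_vecs,
            mch_labels=mch_labels,
        )

    def active_energy_gradient(self, q, k: int):
        """Fast path: eigenvalues and the gradient of surface ``k`` only.

        Used by the nuclear micro-stepping; skips the MCH analysis of
        :meth:`evaluate`.
        """
        H = self.potential_matrix(q)
        evals, evecs = np.linalg.eigh(H)
        v = evecs[:, k]
        dH = self._dH_dq(np.asarray(q, dtype=float))
        grad = np.real(np.einsum("a,iab,b->i", v.conj(), dH, v))
        return evals, grad

    # -- Cartesian reconstruction ---------------------------------------
    def cartesian_geometry(self, q: np.ndarray) -> np.ndarray:
        """Reference geometry displaced along the modes, in Angstrom.

        Delta r = sum_i q_i * sqrt(1/(mu_i w_i)) * disp_i  (bohr -> A).
        """
        if self.reference_geometry is None:
            raise ValueError("model carries no reference geometry")
        geo = self.reference_geometry.copy()
        for qi, mode in zip(np.asarray(q, dtype=float), self.modes):
            geo = geo + qi * mode.cartesian_amplitude * units.ANGSTROM_PER_BOHR * mode.displacement
        return geo


def build_lvc_model(config: dict) -> VibronicModel:
    """Construct a :class:`VibronicModel` from a structured parameter set.

    Expected keys (interface units: eV, cm^-1, amu, Angstrom)::

        states: [{label, multiplicity}, ...]
        energies_eV: {label: float}
        modes: [{freq_cm1, character, reduced_mass_amu, displacement}, ...]
        kappa_eV: {label: [per mode]}                 (optional)
        lambda_eV: {"A|B": [per mode]}                (optional)
        soc_eV: {"A|B": float or [re, im]}            (optional)
        triplet_components: 1 or 3                    (optional)
        reference_geometry: {symbols, coords_angstrom} (optional)
    """
    try:
        states = [StateLabel(s["label"], int(s["multiplicity"]))
                  for s in config["states"]]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"invalid states section: {exc}") from exc
    labels = [s.label for s in states]
    if len(set(labels)) != len(labels):
        raise ModelValidationError("duplicate state labels")
    nb = len(states)

    energies = np.array([float(config["energies_eV"][lb]) for lb in labels])
    if not np.all(np.isfinite(energies)):
        raise ModelValidationError("non-finite energies")
    energies *= units.HARTREE_PER_EV

    modes = []
    for k, m in enumerate(config["modes"]):
        disp = m.get("displacement")
        if disp is None:
            disp = np.zeros((1, 3))
            disp[0, 0] = 1.0
        modes.append(NormalMode(
            index=int(m.get("index", k + 1)),
            frequency=float(m["freq_cm1"]) * units.HARTREE_PER_CM1,
            displacement=np.asarray(disp, dtype=float),
            character=m.get("character", IN_PLANE),
            reduced_mass=float(m.get("reduced_mass_amu", 1.0)) * units.AMU_TO_AU,
        ))
    nm = len(modes)

    kappa = np.zeros((nb, nm))
    for lb, row in (config.get("kappa_eV") or {}).items():
        kappa[labels.index(lb)] = np.asarray(row, dtype=float) * units.HARTREE_PER_EV

    lam = np.zeros((nb, nb, nm))
    for key, row in (config.get("lambda_eV") or {}).items():
        a, b = (labels.index(x) for x in key.split("|"))
        lam[a, b] = lam[b, a] = np.asarray(row, dtype=float) * units.HARTREE_PER_EV

    soc = np.zeros((nb, nb), dtype=complex)
    for key, val in (config.get("soc_eV") or {}).items():
        a, b = (labels.index(x) for x in key.split("|"))
        v = complex(val[0], val[1]) if isinstance(val, (list, tuple)) else complex(val)
        soc[a, b] = v * units.HARTREE_PER_EV
        soc[b, a] = np.conj(v) * units.HARTREE_PER_EV

    ref = config.get("reference_geometry")
    ref_geo = symbols = None
    if ref is not None:
        ref_geo = np.asarray(ref["coords_angstrom"], dtype=float)
        symbols = list(ref["symbols"])

    return VibronicModel(
        states=states, energies=energies, kappa=kappa, lam=lam, soc=soc,
        modes=modes,
        triplet_components=int(config.get("triplet_components", 1)),
        reference_geometry=ref_geo, atom_symbols=symbols,
        metadata=config.get("metadata"),
    )
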