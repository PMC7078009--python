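# Methods

## Model

The electronic structure is a linear vibronic coupling (LVC) model over
harmonic normal modes, augmented with constant spin–orbit couplings
(SOC). In dimensionless (mass–frequency-scaled) coordinates q with
conjugate momenta p, the Hamiltonian matrix over diabatic states is

    H_nn(q) = ε_n + Σ_i (ω_i/2) q_i² + Σ_i κ_i⁽ⁿ⁾ q_i
    H_nm(q) = Σ_i λ_i⁽ⁿᵐ⁾ q_i      (same spin multiplicity)
    H_nm    = V_SO⁽ⁿᵐ⁾             (singlet–triplet pairs, q-independent)

and the nuclear kinetic energy is Σ_i (ω_i/2) p_i². Everything internal
is in atomic units (ħ = 1); interfaces use eV, fs, Å and cm⁻¹, with the
conversion constants collected in `thiohop.units`.

Two electronic representations are kept throughout:

* **MCH** states — eigenstates of the spin-free blocks (pure
  multiplicity), labeled S₀…T₂ by their dominant diabatic character;
* **diagonal** states — eigenstates of the full matrix including SOC,
  ordered by energy. Trajectories are propagated in this basis.

Triplets enter as one effective component by default
(`triplet_components = 1`); the scalar V_SO is then interpreted as the
root-sum-square of the three sublevel couplings. Setting
`triplet_components = 3` expands each triplet into three degenerate
sublevels sharing the SOC constant, with λ couplings acting within
matching sublevels.

Eigenvector phases are fixed deterministically (largest component real
positive) and then phase-tracked between consecutive geometries by
maximal overlap, which keeps the overlap-based electronic propagation
stable.

## Default model

The default configuration is a synthetic five-state, six-mode stand-in
for 2-thiopyridone. Its fixed ingredients:

* Vertical energies (eV): S₁ 3.16, S₂ 3.82, T₁ 2.64, T₂ 2.90 (the
  CASPT2-corrected values are stored as metadata only).
* A planar 12-atom reference skeleton (hexagonal ring N + 5C with S on
  the carbon adjacent to N, one N–H and four C–H bonds) with
  r(N–H) = 1.03 Å and r(S–H) ≈ 2.80 Å at the reference.
* Six orthonormal modes: ring torsion (420 cm⁻¹) and N–H wag
  (560 cm⁻¹), both out-of-plane; ring breathing (980 cm⁻¹), N–H rock
  (1260 cm⁻¹), ring stretch (1560 cm⁻¹) and N–H stretch (3280 cm⁻¹),
  in-plane. The N–H wag (mode 2) is the phase-alignment reference.

The coupling magnitudes (κ, λ, V_SO) are illustrative: no published
values exist for this system, so they were chosen once to reproduce the
qualitative photophysics — ultrafast S₂→S₁ internal conversion driven by
in-plane vibronic coupling (λ up to 0.1 eV between the singlets), slower
intersystem crossing through constant SOC of heavy-atom magnitude
(0.006–0.04 eV, i.e. ≲320 cm⁻¹ as sublevel root-sum-squares), and
triplet-manifold mixing through out-of-plane λ. They are not fitted to
any reference populations. Out-of-plane κ components vanish by the
planar symmetry of the reference.

## Initial conditions

The vibrational ground state of each harmonic mode has the Gaussian
Wigner density with Var(q) = Var(p) = 1/2, so sampling is exact:
independent normal draws per mode, no thermal excitation. One global
integer seed spawns per-trajectory sub-seeds (numpy `SeedSequence`),
each recorded on its sample, so any single trajectory can be re-run in
isolation. The same sub-seed also seeds that trajectory's hop-decision
stream.

## Propagation

Each classical step of length dt (default 0.5 fs):

1. **Nuclear step** — velocity Verlet on the active diagonal surface
   with Hellmann–Feynman gradients (exact for eigenvalues; SOC is
   constant and contributes nothing). If the one-step total-energy error
   exceeds `step_energy_tol` (default 10⁻⁶ Hartree) the step is redone
   with 4, 16, … 64 velocity-Verlet micro-steps. This safeguard exists
   because the diagonal surfaces of an LVC+SOC model have avoided
   crossings whose width (set by V_SO, down to ~10⁻⁴ Hartree) is far
   smaller than the distance traveled per step; integrating across such
   a kink in one 0.5 fs step produces energy jumps of ~5·10⁻⁴ Hartree
   regardless of the SOC magnitude chosen. With the safeguard the net
   energy error between hops stays below ~10⁻⁵ Hartree.
2. **Electronic step** — local diabatization: the overlap
   S = U(t)ᵀ U(t+dt) of consecutive eigenvector sets is
   Löwdin-orthogonalized (T = S(SᵀS)^(−1/2), computed via SVD) and the
   amplitudes advance as c ← T† Π_m exp(−i H̄_m δt) c with
   δt = dt/substeps (default 100) and H̄_m the diagonal energies
   linearly interpolated across the step.
3. **Hop decision** — fewest-switches probabilities from the step
   propagator A: the fractional loss of active population is apportioned
   among targets by the cross terms Re(c′_β A*_βα c*_α), clamped at
   zero, capped at the total loss, and tested against one uniform
   variate. On a hop the potential gap (diagonal energies at the new
   geometry) is absorbed by rescaling the momentum vector along itself;
   if the kinetic energy cannot cover the gap the hop is frustrated and
   the momentum is kept (default) or reflected. Energy is conserved
   exactly across successful hops.
4. **Decoherence** — energy-based damping of non-active amplitudes with
   τ_k = (1/|E_k − E_act|)(1 + C/E_kin), C = 0.1 Hartree, applied after
   the hop decision; the active amplitude is rescaled to restore unit
   norm. Steps with zero kinetic energy skip the correction and log it.

Hops are recorded with both diagonal indices and MCH labels (the
dominant MCH parent of the diagonal state at the hop geometry). The
hop-preceding geometry stored with each event is the frame at the
beginning of the classical step in which the hop fired.

The electronic wavefunction starts as the requested pure MCH state
expressed in the diagonal basis; the initially active surface is the
diagonal state of largest initial population.

## Ensemble kinetics

Populations are computed in three bases: fraction of trajectories whose
active diagonal state (`diagonal_active`) or MCH assignment
(`mch_active`) carries a label, and the ensemble mean of |c_k|²
(`quantum_amplitude`, reported in MCH labels with triplet sublevels
merged). All sum to one by construction.

The kinetic model is a first-order mass-action network over six latent
species {S₀, S₁, S₁′, S₂, T₁, T₂} with nine rate constants: main forward
S₂→S₁→T₂→T₁, the three corresponding backward steps, and minority
S₂→S₁′, S₁′→S₀, S₂→T₂. S₁′ tags the sub-population destined for ground
state recovery; observably it is reported inside S₁, so the fit sees
five observable series. The linear ODE system is solved with matrix
exponentials (one `expm` and repeated stepping on uniform grids), which
conserves total population to machine precision.

Fitting choices:

* unweighted least squares over all observable species × time points;
* rates bounded to [0, 1] fs⁻¹; multi-start local optimization (default
  10 starts, log-uniform in [10⁻⁵, 10⁻¹] fs⁻¹, seeds logged);
* a negligible ridge term (10⁻⁶·k per rate in the residual vector) plus
  an identifiability pruning pass: a rate whose removal leaves the data
  SSE unchanged is reported as exactly zero. Rates out of species that
  never acquire population are otherwise unidentifiable;
* confidence intervals, when requested, by trajectory-level bootstrap
  (200 resamples, warm-started refits).

The singlet-manifold lifetime model is P(t) = exp(−t/τ) fitted to the
summed manifold population by least squares with τ > 0 (log-linear
initialization, tight tolerances); a non-decaying series is flagged
`converged = False` rather than given a lifetime. The standard error,
when an ensemble is supplied, comes from a trajectory bootstrap.

Mean first-hop times average the first matching hop time per trajectory;
trajectories without the hop are excluded and counted.

## Structural analysis

Projections are mass-unweighted Cartesian scalar products
p_i = (r − r_ref)·d̂_i with unit-normalized mode vectors, in Å; this
convention (and the population-σ convention of the hop statistics) is
stamped into every output header. No rotational pre-alignment is applied
by default; a Kabsch alignment flag exists and its use is recorded. For
a planar molecule the sign of an out-of-plane distortion is arbitrary,
so geometries are optionally mirrored to a positive phase of a reference
out-of-plane mode by flipping the sign of all out-of-plane projections;
in-plane projections are mirror-invariant. MECP comparisons report
|μ − p_MECP| for in-plane modes and, for out-of-plane modes, whether
|p_MECP| ≤ |μ| + 2σ (the sign being meaningless there). Bond lengths are
Euclidean distances of named atoms in geometries reconstructed as
r_ref + Σ_i q_i (μ_i ω_i)^(−1/2) d̂_i.

## What the synthetic generator does and does not emulate

The default model reproduces: the state count and Franck–Condon
energies; ultrafast in-plane-driven internal conversion followed by
slower SOC-mediated intersystem crossing with forward and backward
transitions; in-plane/out-of-plane mode families with an N–H-centred
out-of-plane reference mode; realistic bond-length scales and
zero-point-level fluctuations.

It does not emulate: anharmonicity or bond breaking (no proton-transfer
events can occur by construction); the full 30-mode density of states of
the real molecule — with six modes the excess energy per mode after
relaxation is several times larger, which exaggerates recrossing and
surface-hop counts; geometry-dependent SOC; solvent. Passing tests
therefore validate the algorithms and analyses, not quantitative
observables of the real system: lifetimes, hop counts and hop-geometry
statistics from the default model are qualitative only.

## Problem sizes and numerics

The test suite and the acceptance script use: 100 trajectories × 1 ps at
dt = 0.5 fs with 100 electronic substeps for ensemble-level results; 10
trajectories for conservation checks; 10⁵ samples for Wigner moments; 50
seeded repeats at n = 1000 for noisy rate recovery; 100 random fixtures
for projection algebra. Tolerances: Hermiticity and unitarity 10⁻¹²/10⁻¹⁰;
analytic vs finite-difference gradients 10⁻⁶; amplitude norm 10⁻⁸
(exactly renormalized after decoherence); energy drift 10⁻⁴ Hartree
between hops; ODE/Bateman closed forms 10⁻⁸/10⁻⁶. Ties and degeneracies:
eigenvalues ascending; degenerate decoherence gaps skip damping;
hop probabilities clamp at zero and cap at the actual population loss.
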