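# thiohop

Spin–orbit surface hopping on analytic vibronic models, with the ensemble
analysis used to characterize ultrafast intersystem crossing in
photo-excited thiocarbonyl heteroaromatics such as 2-thiopyridone (2-TP).

## The problem

UV excitation of 2-TP populates the bright S₂(π,π\*) state, which relaxes
within tens of femtoseconds to S₁(n,π\*) and then crosses — despite the
transition being El-Sayed forbidden — into the triplet manifold
(T₂, T₁) on a picosecond timescale. Resolving this cascade requires
trajectory surface hopping with spin–orbit coupling, plus a set of
ensemble analyses: state populations and a kinetic rate-network fit,
surface-hop bookkeeping, a single-exponential lifetime of the singlet
manifold, and normal-mode decompositions of the geometries that drive each
transition.

`thiohop` implements that entire tool chain at desk scale. The ab initio
surfaces are replaced by a linear vibronic coupling (LVC) model: for
dimensionless mode coordinates *q* and states *n*, *m* of equal spin
multiplicity,

    H_nn(q) = ε_n + Σ_i (ω_i/2) q_i² + Σ_i κ_i⁽ⁿ⁾ q_i
    H_nm(q) = Σ_i λ_i⁽ⁿᵐ⁾ q_i

with constant spin–orbit couplings V_SO between singlet–triplet pairs.
Nuclei move classically on an eigensurface of the full spin-mixed
("diagonal") Hamiltonian; electronic amplitudes are propagated with the
local-diabatization (wavefunction overlap) scheme; fewest-switches hops,
an energy-based decoherence correction and momentum rescaling complete
the SHARC-style algorithm. The default model is a five-state
(S₀, S₁, S₂, T₁, T₂), six-mode stand-in for 2-TP whose vertical energies
are the Franck–Condon values 3.16, 3.82, 2.64 and 2.90 eV for
S₁, S₂, T₁, T₂.

## Worked example

```python
import numpy as np
import thiohop as th

model = th.default_model()
inits = th.sample_wigner(model.modes, 20, "S2", seed=7)
ens = th.propagate_ensemble(model, inits, th.PropagationParams(t_max_fs=500.0))

grid = np.linspace(0, 500, 101)
pops = th.compute_populations(ens, "mch_active", grid)
print(pops.data.iloc[::25])
print(th.fit_exponential_manifold(pops, ["S0", "S1", "S2"]).summary())
```

prints

```
          S0    S1    S2   T1    T2
time_fs
0.0      0.0  0.00  1.00  0.0  0.00
125.0    0.0  0.85  0.15  0.0  0.00
250.0    0.0  0.75  0.10  0.1  0.05
375.0    0.0  0.65  0.15  0.1  0.10
500.0    0.0  0.60  0.10  0.1  0.20
Exponential manifold decay fit (S0+S1+S2)
  converged: True
  lifetime tau = 1661.4 fs
  SSE = 1.996387e-01
```

Twenty trajectories start in S₂ from ground-state Wigner initial
conditions; by 125 fs most of the ensemble has undergone S₂ → S₁ internal
conversion, and the triplet states then fill in over hundreds of
femtoseconds. The summed singlet population is well described by a single
exponential with a picosecond-scale lifetime — the headline observable of
this kind of simulation. `th.count_hops(ens).render(...)` prints the
surface-hop matrix with the main relaxation pathway
S₂ → S₁ → T₂ → T₁ highlighted and sub-threshold entries suppressed.

The same pipeline runs from the shell:

```sh
thiohop report --out run1 --n-traj 100 --seed 2020
```

writes population tables (three state representations), the hop matrix,
the nine-rate kinetic fit, the exponential manifold fit, hop-geometry
statistics, per-mode coherence series, bond-length series and figures into
`run1/`, together with a `manifest.json` carrying the config hash and seed.

## Layout

| module | contents |
|---|---|
| `thiohop.vibronic` | LVC + SOC Hamiltonian, diagonalization, gradients |
| `thiohop.wigner` | ground-state Wigner sampling of initial conditions |
| `thiohop.propagate` | surface-hopping propagator, decoherence, hops |
| `thiohop.kinetics` | populations, hop matrix, `KineticModel`/`ExponentialDecayModel` fits |
| `thiohop.structure` | mode projections, phase alignment, coherence, bonds, MECP comparison |
| `thiohop.io`, `thiohop.cli`, `thiohop.pipeline` | Molden/XYZ/config I/O, CLI, report bundles |

See `docs/methods.md` for the model definition, algorithmic conventions
and the limitations of the synthetic surfaces.
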