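# nqekit

Desk-scale toolkit for studying how **nuclear quantum effects (NQE)** —
zero-point motion and thermal delocalization of atomic nuclei — strengthen
covalent and non-covalent molecular interactions. Counterintuitively,
nuclear delocalization does not simply smear dynamics out: by dilating bond
lengths and reshaping free-energy landscapes it can *localize* molecular
motion (a methyl rotor transiently stops rotating), pull partially charged
atoms closer (stronger electrostatics), and inflate molecular volume and
polarizability (stronger van der Waals dispersion).

The package is aimed at method developers and students who want a small,
fully tested implementation of the complete chain: learn a force field from
forces, sample it classically and quantum-mechanically, and measure the
interaction-strengthening observables.

## What's inside

* **Gradient-domain force field** (`nqekit.forcefield`) — kernel regression
  of the energy trained on forces: a Gaussian process over inverse-distance
  descriptors with a Matérn 5/2 kernel, so the predicted forces are the
  exact analytic negative gradient of one scalar energy (energy
  conservation by construction) and an explicit atom-permutation group is
  averaged into the kernel (permutational invariance as a prior).
  Statsmodels-style interface: `GDML(dataset, sigma, lam).fit()` returns a
  `GDMLResults` with `predict`, diagnostics and `summary()`.
* **Classical & path-integral MD** (`nqekit.dynamics`, `nqekit.fastpath`) —
  ring-polymer Langevin dynamics (OBABO splitting in free-ring-polymer
  normal modes, ω_k = 2ω_P sin(kπ/P)); P = 1 is exactly classical Langevin.
  Quantum kinetic energies via primitive and centroid-virial estimators:
  on a harmonic oscillator the sampled total energy converges to
  (ħω/2)·coth(βħω/2). A numba-compiled path handles multi-nanosecond runs
  on the model surfaces.
* **Model potentials** (`nqekit.potentials`) — analytic stand-ins with
  exact gradients for the mechanisms under study: a six-fold methyl-rotor
  surface that a ring-bond dilation δd transforms into a three-fold surface
  (barrier 0.024 → up to 0.55 kcal/mol ≈ kB·T at 300 K), a steep r⁻¹¹
  lone-pair→π* attraction behind a repulsive wall, a partial-charge O⋯H
  Coulomb toy slaved to a torsion, Morse dimers with damped dispersion
  tails, and a Metropolis Boltzmann sampler that generates training sets
  with exact energies/forces.
* **Analysis** (`nqekit.analysis`) — dihedral angles, free-energy surfaces
  by Boltzmann inversion (−kB·T·ln ρ, empty bins masked), time–angle
  occupancy maps (5 ps × 6° bins), localized-rotor-state detection,
  log–log power-law tail fits, and a Casimir–Polder dispersion toolkit:
  C6 = (3ħ/π)∫α_A(iω)α_B(iω)dω for Drude oscillators, the α ∝ R⁷
  radius–polarizability surrogate, and ensemble-averaged interaction scans.
* **I/O + CLI** (`nqekit.io`, `nqekit.cli`) — extended XYZ, the z/R/E/F
  compressed dataset dialect of the published gradient-domain training
  sets, trajectory containers, YAML configs, and `nqekit
  fixtures/train/predict/md/pimd/analyze` subcommands with structured run
  logs.

## Worked example

Train a force field on Boltzmann-sampled dimer data, then compare classical
and quantum sampling of the bond-coupled methyl rotor:

```python
import numpy as np
from nqekit.data import PermutationGroup
from nqekit.forcefield import GDML
from nqekit.potentials import MorseDimerPES, RotorBondPES, sample_training_set
from nqekit.fastpath import run_trajectory_fast
from nqekit.analysis import detect_localized_states

pes = MorseDimerPES()
data = sample_training_set(pes, T=300.0, n=300, seed=1,
                           x0=np.array([0, 0, 0, pes.re, 0, 0.0]))
res = GDML(data[:200], sigma=1.0, lam=1e-10,
           permutations=PermutationGroup([[1, 0]], 2)).fit()
print(res.summary())          # train force MAE ~1e-6 kcal/mol/A
e, f = res.predict(data[250]) # held-out force MAE ~0.0008 kcal/mol/A

rotor = RotorBondPES()        # V6 = 0.024 kcal/mol; V3 calibrated to 0.55
for P in (1, 32):             # classical vs path-integral (32 beads)
    traj = run_trajectory_fast(rotor, [0.1, 0.0], T=300.0, P=P, dt=0.2,
                               steps=10_000_000, stride=25, seed=4,
                               thermostat_time=1000.0)
    theta = np.degrees(traj.frames[:, 0])
    _, s = detect_localized_states(theta, traj.dt * traj.stride,
                                   [0, 120, -120], 30.0, 1000.0)
    print(P, s["rate_per_ns"], "localized states per ns")
```

Output of a run of this kind (2 ns per trajectory, seed 4):

```
classical:    50 localized states (25.0/ns), three-fold amplitude |c3| = 0.020
quantum P=32: 54 localized states (27.0/ns), three-fold amplitude |c3| = 0.039
```

The quantum rotor stops more often and its angle histogram develops the
three-fold structure that the classical run lacks — the six-fold→three-fold
barrier transformation driven by quantum bond dilation. (Longer runs
sharpen the contrast; the 4 ns fixed-seed comparison in the test suite
gives 20.3/ns vs 32.0/ns.) For dispersion, a 2% dilated ensemble deepens
the C6/R⁶ interaction scan uniformly by ~13%:

```
[dispersion] Drude C6 quadrature 796.88 vs London closed form 796.88 kcal/mol*A^6
[dispersion] dilated-ensemble scan deeper by 13.2% across R = 4-10 A
```

## End-to-end script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch — samples training data, trains
and validates the force field, runs classical and path-integral dynamics on
the harmonic-oscillator, rotor and charge-pair systems, fits the r⁻¹¹ tail,
and evaluates the Casimir–Polder dispersion model — printing each number it
obtains (~2 minutes). The JSON it writes records the externally compared
target set.

## Units

Å, amu, fs internally; energies in kcal/mol and angles in degrees at every
public interface. kB·300 K ≈ 0.6 kcal/mol is the yardstick against which
all torsional barriers in this package are judged.

See `docs/methods.md` for the models, calibrations, estimator formulas,
and the limitations of the synthetic world.
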