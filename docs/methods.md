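# Methods

`nqekit` is a desk-scale toolkit for studying how nuclear quantum effects
(NQE) — zero-point motion and thermal delocalization of the nuclei — modify
covalent and non-covalent molecular interactions. It combines four pieces:
a gradient-domain kernel force field trained on forces, classical and
path-integral molecular dynamics (PIMD), calibrated analytic model
potentials that stand in for quantum-chemistry reference surfaces, and the
analysis operators used to compare classical and quantum sampling.

Internal units are Å, amu, fs, radians; public interfaces use kcal/mol and
degrees. Constants derive from CODATA 2018 (`nqekit.units`), with
kB = 0.0019872 kcal·mol⁻¹·K⁻¹ and ħ = 15.1787 (kcal/mol)·fs.

## Gradient-domain force field

The latent energy E(x) is a Gaussian process over the inverse-distance
descriptor D(x) = {1/‖r_a − r_b‖}_{a<b} with a Matérn ν = 5/2 kernel
k(d) = (1 + √5d/σ + 5d²/3σ²)e^{−√5d/σ} on descriptor distances. Training
observes forces F_i = −∇E(x_i): the Gram matrix consists of kernel second
derivatives ∇_x∇_{x'}k carried through the descriptor Jacobians, and the
predictor

    F̂(x) = K_FF(x, X) α,   Ê(x) = −Σ_j [∇_{x_j} k(x, x_j)]ᵀ α_j + c,

is by construction the negative analytic gradient of one scalar function —
energy conservation is a structural prior, not a fitted property. An
explicit, user-supplied atom-permutation group symmetrizes the kernel
(k_sym = group average), building permutational invariance in exactly.

Choices and rationale:

* **Kernel.** Matérn 5/2 is the least-smooth kernel whose force–force
  covariance exists (twice differentiable at the origin); rougher members
  would make the Gram matrix undefined, smoother ones (RBF) are
  numerically stiffer. All derivative expressions are closed-form and
  smooth through zero descriptor distance.
* **Solve.** Cholesky factorization of K + λI; when factorization fails at
  λ > 0 a jitter of 1e−10·mean(diag K) is added once with a warning; at
  λ = 0 a singular system raises with a condition estimate.
* **Energy offset.** Forces determine E only up to a constant; c is set by
  mean-matching predicted and reference training energies when energies are
  present, else 0.
* **Scaling.** The Gram matrix is (3NM)²; a memory guard (default 4 GB)
  refuses larger systems. Training sets of ~1000 configurations — the size
  at which gradient-domain models typically saturate — fit within that
  budget for small molecules; the
  test suite and the end-to-end script use 80–200 configurations of a
  two-atom dimer, which already sits far below the generalization bounds
  (held-out energy MAE ≤ 0.2 kcal/mol, force MAE ≤ 0.7 kcal/mol/Å).
* **Hyperparameters.** `select_hyperparameters` is this package's own
  protocol — grid
  search minimizing validation force MAE on a seeded split, ties broken
  toward smallest σ then smallest λ, every candidate logged.

## Path-integral molecular dynamics

Each nucleus is represented by P beads coupled by harmonic springs; the
ring polymer carries the full physical potential on every bead with spring
frequency ω_P = P/(βħ) and is thermostatted at P·T (the standard
path-integral Langevin convention; an equivalent formulation scales the
potential by 1/P and thermostats at T — the stationary statistics are
identical). Propagation is the OBABO splitting: half Langevin step in
free-ring-polymer normal modes (per-mode friction γ_k = 2ω_k, centroid
friction 1/τ with τ the `thermostat_time`, default 100 fs), half momentum
kick, exact free-ring-polymer normal-mode evolution, and the mirrored
halves. P = 1 reduces exactly to classical Langevin dynamics and, with the
thermostat off, to velocity Verlet (tested: energy drift < 1e−6
kcal/mol/period at dt = period/1000).

Quantum energies are reported with both the primitive and the
centroid-virial kinetic estimators,

    KE_prim = 3NP/2β − (1/P) Σ_j ½mω_P²(q_j − q_{j+1})²,
    KE_vir  = 3N/2β + (1/2P) Σ_j (q_j − q̄)·∇V(q_j),

averaged over frames with block-averaged (20 blocks) standard errors. On a
harmonic oscillator with βħω = 5, P = 32 reproduces (ħω/2)coth(βħω/2)
within 5% (test); stationary bead covariances match the analytic Gaussian
normal-mode integrals for P ∈ {1, 2, 4, 8}.

Defaults follow the standard production protocol for these systems:
dt = 0.2 fs, T = 300 K,
runs of ≥ 500 ps for production mechanism studies; the bead ramp
P ∈ {1, 4, 8, 16, 32} is the documented convergence protocol (virial energy
changing < 1% between successive P declares convergence;
`bead_convergence_ramp`). Thermostat parameters and production bead counts
have no universal values; the defaults here are this package's documented
choices.

The `fastpath` module JIT-compiles the identical OBABO splitting for the
closed-form surfaces (rotor, harmonic, double well), keeping the state in
normal modes; it exists purely because the multi-nanosecond rotor studies
need ~10⁷–10⁸ force evaluations. It uses an independent noise stream, so
only distributions, not trajectories, coincide with the generic integrator
(asserted statistically in the tests). The two adjacent O half-steps at
each step boundary are composed into one exact full Ornstein–Uhlenbeck
step; position-dependent records are unaffected.

## Model potentials (the synthetic world)

These surfaces encode the mechanisms under study with exact gradients; they
are calibrated stand-ins, not fits to any molecule.

* **Bond-coupled methyl rotor** (θ, δd):
  V = (V6/2)(1 − cos 6θ) + (V3·max(δd, 0)/2)(1 − cos 3θ) + (k/2)δd².
  V6 = 0.024 kcal/mol is the coupled-cluster six-fold barrier of a
  toluene-like rotor; the rectified coupling turns positive dilation of the
  neighbouring ring bond into a three-fold barrier — the six-fold → three-fold transformation of
  the rotor surface under ring-bond dilation. Bond stiffness k = 1302
  kcal/mol/Å² (an aromatic C–C stretch near 1600 cm⁻¹ at reduced mass
  6 amu), rotor inertia 3.2 amu·Å² (three H at ~1 Å from the axis). V3 is
  calibrated once, analytically: the total barrier reaches 0.55 kcal/mol —
  the maximum barrier the quantum rotor is meant to experience, comparable to kB·T — at
  δd = 2σ_q, where σ_q = √[(ħ/2mω)coth(βħω/2)] ≈ 0.042 Å is the quantum
  bond-length spread at 300 K (V3 ≈ 6.27 kcal/mol/Å). The anticorrelated
  second bond (d ≈ −s·δd) is reported as an observable, not integrated.
  The linear dependence of the three-fold amplitude on dilation is a
  modelling choice; the reference data for the real molecule are only
  graphical.
* **Lone-pair → π\* toy**: E(r) = B e^{−r/ρ} − A·g(φ)·r⁻¹¹, a steep
  attraction behind an exponential wall, with B fixed so the minimum sits
  at r_eq = 2.9 Å and the overlap gate g(φ) = (1 + cos φ)/2 extinguishing
  the attraction at φ = 180°. The tail has exact log–log slope −11, the
  exponent the power-law fitter must recover.
* **Charge-pair toy**: a partially charged O⋯H pair whose distance is
  geometrically slaved to a torsion, d(φ, s) = d_far − swing·(1 + cos φ)/2
  + s, with bare Coulomb attraction (k_C = 332.06 kcal·Å/mol/e²,
  q_O = −0.55 e, q_H = +0.20 e), a short-range wall and a harmonic radial
  breathing coordinate — the minimal model of electrostatic strengthening
  through correlated (distance, dihedral) dynamics.
* **Morse dimer with damped dispersion**: Morse bond plus a −C6/r⁶ tail,
  Fermi-damped (midpoint 2.0 Å, width 0.25 Å) to remove the r → 0
  divergence; the force-field training target.

**Boltzmann sampler.** `sample_training_set` is a Metropolis random walk
targeting exp(−V/kBT), step size adapted toward ~40% acceptance during
burn-in and frozen afterwards (detailed balance holds for all recorded
samples); every record carries the exact analytic energy and forces.
Acceptance rates outside [0.05, 0.95] trigger an ergodicity warning. The
sampler reproduces equipartition and the analytic harmonic marginal
(Kolmogorov–Smirnov checked) on the solvable fixtures.

## Analysis operators

* **Free-energy surfaces**: F = −kB·T·ln(ρ/ρ_max) on occupied histogram
  bins, minimum 0; empty bins are masked, never zero-filled or imputed.
* **Localized rotor states**: maximal intervals in which the wrapped angle
  stays within ±30° (default) of one well center for ≥ 1 ps (default);
  durations use closed-interval semantics (first-to-last frame, equality
  counts). There is no canonical quantitative criterion for a localized
  state — the thresholds are exposed parameters — and the time–angle
  occupancy map defaults to 5 ps × 6° bins.
* **Power-law fits**: ordinary least squares of log|E| on log r inside
  [r_min, r_max] (default r_min = 3.8 Å, the attractive-tail convention);
  a sign change inside the window raises with instructions to move the
  window past the minimum.
* **Casimir–Polder dispersion**: C6 = (3ħ/π)∫α_A(iω)α_B(iω)dω by 200-node
  Gauss–Legendre quadrature on ω = ω_s t/(1 − t); for Drude
  polarizabilities α(iω) = α₀ω₀²/(ω₀² + ω²) this matches the London closed
  forms to < 1e−6 relative. E_vdW = −C6/R⁶.
* **Polarizability surrogate**: per-configuration α ∝ R⁷ with R the
  mass-weighted radius of gyration plus a fixed 1.5 Å electron-margin
  offset. Ab initio polarizability tensors are out of scope; the surrogate
  preserves the scaling mechanism (volume dilation → polarizability gain →
  stronger dispersion) and only relative dilations between ensembles are
  meaningful. Full 3×3 tensors are accepted where available (isotropic
  part = Tr/3).
* **Ensemble interaction scans**: mean ± SE of a pair potential over
  index-paired (default, size 50) or cross-paired configuration ensembles
  held at fixed fragment separation.

## What the synthetic world does and does not establish

The generator emulates: Boltzmann-distributed training sets with exact
forces; the six-fold → three-fold torsional transformation driven by bond
dilation; a steep r⁻¹¹ attraction with a repulsive wall; a partial-charge
electrostatic toy with torsion–distance coupling; and geometry ensembles
whose effective radii dilate under quantum relative to classical sampling.
It does **not** contain real electronic structure: no orbital interactions,
no ab initio polarizabilities or SAPT decompositions, no full-dimensional
molecular surfaces. A green mechanism test therefore establishes that the
*pipeline* (PIMD sampling + estimators + analysis operators) reproduces the
physical mechanism on a model with the stated structure — quantum bond
delocalization localizes the rotor and dilated ensembles strengthen C6/R⁶
scans — not that any specific molecule's numbers are reproduced. Per-molecule
electronic-structure quantities (orbital-interaction energies of several
kcal/mol, percent-level polarizability increments, SAPT dimer curves)
require external quantum-chemistry programs and are out of scope.

## Numerical notes and limitations

* The rotor's rectifier max(δd, 0) makes ∂V/∂δd discontinuous at δd = 0;
  gradient finite-difference checks probe away from the kink, and the
  Langevin integrator is insensitive to the measure-zero discontinuity.
* Ring-polymer normal modes come from diagonalizing the ring Laplacian;
  degenerate mode pairs admit any orthogonal basis — all propagated
  quantities are invariant to that choice.
* RNG: one master seed per run; initialization and thermostat streams are
  derived from it and recorded in trajectory provenance. Fixed seeds make
  every simulation in the tests and the end-to-end script reproducible.
* The classical rotor also shows occasional ≥1 ps dwells (it is a rare
  event even classically); the quantum effect is a
  robust *increase* in their rate plus emergent three-fold histogram
  structure, and the tests assert exactly that ordering, not absolute
  counts.
* No ring-polymer contraction, colored-noise thermostats, replica exchange
  or constant-pressure sampling; no deuteration switch; no automatic
  permutation-group discovery (groups are supplied explicitly).
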