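"""Classical Langevin and ring-polymer (path-integral) molecular dynamics.

Quantum thermal statistics of the nuclei are recovered by sampling a ring
polymer of P replicas ("beads") per particle, coupled by harmonic springs.
The extended system is propagated with the OBABO splitting: half Langevin
thermostat in free-ring-polymer normal modes, half momentum kick from the
physical forces, exact free-ring-polymer evolution, and the mirror halves.
P = 1 reduces exactly to classical Langevin dynamics (and, with the
thermostat off, to velocity Verlet).

Convention: the ring polymer carries the full physical potential on every
bead with spring frequency ω_P = P/(βħ) and is thermostatted at P·T (the
standard path-integral Langevin setup). Quantum kinetic energies are
reported through the primitive and centroid-virial estimators.

Positions are in Å (or the model surface's native coordinates), masses in
amu, times in fs; reported energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .units import HBAR_INT, INT_TO_KCAL, KB, KB_INT, KCAL_TO_INT, thermal_energy

__all__ = [
    "thermal_energy", "PIMDState", "Trajectory", "init_state", "pimd_step",
    "run_trajectory", "kinetic_estimators", "normal_mode_frequencies",
    "ring_polymer_covariance", "bead_convergence_ramp",
]

ForceProvider = Callable[[np.ndarray], tuple[float, np.ndarray]]


def normal_mode_frequencies(P: int, T: float) -> np.ndarray:
    """Free ring-polymer normal-mode frequencies ω_k = 2 ω_P sin(kπ/P), fs⁻¹.

    Sorted ascending; ω_0 = 0 is the centroid mode. ω_P = P/(βħ) with
    β = 1/(kB T).
    """
    beta = 1.0 / (KB_INT * T)
    omega_p = P / (beta * HBAR_INT)
    k = np.arange(P)
    return np.sort(2.0 * omega_p * np.abs(np.sin(math.pi * k / P)))


def _ring_transform(P: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal normal-mode transform C (rows = modes) and eigenvalues.

    Diagonalizes the ring Laplacian; mode order matches
    :func:`normal_mode_frequencies` (ascending frequency, centroid first).
    """
    L = np.zeros((P, P))
    for j in range(P):
        L[j, j] = 2.0
        L[j, (j + 1) % P] -= 1.0
        L[j, (j - 1) % P] -= 1.0
    if P == 1:
        return np.ones((1, 1)), np.zeros(1)
    evals, evecs = np.linalg.eigh(L)
    evals = np.clip(evals, 0.0, None)
    return evecs.T, evals


@dataclass
class PIMDState:
    """Bead-resolved phase-space state of one (possibly abstract) system.

    q, p have shape (P, ndof); masses has shape (ndof,). ``T`` is the
    physical target temperature; the extended ring-polymer system is
    sampled at P·T internally. Momenta are in amu·Å·fs⁻¹.
    """

    q: np.ndarray
    p: np.ndarray
    masses: np.ndarray
    T: float
    rng: np.random.Generator
    energy: Optional[np.ndarray] = None   # per-bead potential, kcal/mol
    grad: Optional[np.ndarray] = None     # per-bead gradient, kcal/mol/Å

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.q.ndim != 2 or self.q.shape != self.p.shape:
            raise ValueError("q and p must both have shape (P, ndof)")
        if self.masses.shape != (self.q.shape[1],):
            raise ValueError("masses must have one entry per degree of freedom")
        if self.P < 1:
            raise ValueError("bead count must be >= 1")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        self._C, evals = _ring_transform(self.P)
        beta = 1.0 / (KB_INT * self.T)
        omega_p = self.P / (beta * HBAR_INT)
        self.omega_k = omega_p * np.sqrt(evals)

    @property
    def P(self) -> int:
        return self.q.shape[0]

    @property
    def ndof(self) -> int:
        return self.q.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.q.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "q": self.q.tolist(), "p": self.p.tolist(),
            "masses": self.masses.tolist(), "T": self.T,
            "rng_state": self.rng.bit_generator.state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PIMDState":
        rng = np.random.default_rng()
        rng.bit_generator.state = d["rng_state"]
        return cls(np.array(d["q"]), np.array(d["p"]), np.array(d["masses"]),
                   float(d["T"]), rng)


def init_state(coords, masses, T: float, P: int, seed: int,
               thermal_spread: bool = False) -> PIMDState:
    """Initial PIMD state: beads at the classical geometry, thermal momenta.

    Momenta are Maxwell-Boltzmann at the ring-polymer sampling temperature
    (P·T; for P = 1 this is the physical temperature, variance m·kB·T per
    degree of freedom). With ``thermal_spread`` the non-centroid modes get
    their free-ring-polymer thermal widths instead of starting collapsed.
    """
    if P < 1:
        raise ValueError(f"bead count must be >= 1, got {P}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    x = np.asarray(coords, dtype=float).reshape(-1)
    masses = np.asarray(masses, dtype=float)
    rng = np.random.default_rng([int(seed), 0x1D])
    q = np.tile(x, (P, 1))
    kTp = KB_INT * P * T
    p = rng.normal(size=(P, len(x))) * np.sqrt(masses * kTp)
    state = PIMDState(q, p, masses, T, rng)
    if thermal_spread and P > 1:
        qnm = state._C @ q
        for k in range(1, P):
            width = np.sqrt(kTp / (masses * state.omega_k[k] ** 2))
            qnm[k] = rng.normal(size=len(x)) * width
        state.q = state._C.T @ qnm
    return state


def _o_half(state: PIMDState, dt: float, thermostat_time: Optional[float]) -> None:
    if thermostat_time is None:
        return
    gamma = 2.0 * state.omega_k.copy()
    gamma[0] = 1.0 / thermostat_time
    c1 = np.exp(-0.5 * dt * gamma)[:, None]
    kTp = KB_INT * state.P * state.T
    sig = np.sqrt((1.0 - c1 ** 2) * state.masses[None, :] * kTp)
    pnm = state._C @ state.p
    pnm = c1 * pnm + sig * state.rng.normal(size=pnm.shape)
    state.p = state._C.T @ pnm


def _a_step(state: PIMDState, dt: float) -> None:
    if state.P == 1:
        state.q = state.q + dt * state.p / state.masses[None, :]
        return
    qnm = state._C @ state.q
    pnm = state._C @ state.p
    m = state.masses[None, :]
    # centroid: free flight
    qnm[0] += dt * pnm[0] / state.masses
    w = state.omega_k[1:, None]
    c, s = np.cos(w * dt), np.sin(w * dt)
    q1 = qnm[1:] * c + pnm[1:] / (m * w) * s
    p1 = pnm[1:] * c - m * w * qnm[1:] * s
    qnm[1:], pnm[1:] = q1, p1
    state.q = state._C.T @ qnm
    state.p = state._C.T @ pnm


def pimd_step(state: PIMDState, force_provider: ForceProvider, dt: float,
              thermostat_time: Optional[float] = None) -> PIMDState:
    """One OBABO step (in place). ``force_provider`` maps a (P, ndof) batch
    of bead coordinates to (per-bead energies kcal/mol, per-bead gradients).

    With P = 1 and the thermostat off this is exactly velocity Verlet on the
    physical surface.
    """
    if dt <= 0:
        raise ValueError(f"time step must be positive, got {dt}")
    if state.grad is None:
        state.energy, state.grad = _eval_batch(force_provider, state.q)
    _o_half(state, dt, thermostat_time)
    state.p -= 0.5 * dt * KCAL_TO_INT * state.grad
    _a_step(state, dt)
    state.energy, state.grad = _eval_batch(force_provider, state.q)
    if not np.all(np.isfinite(state.grad)):
        raise FloatingPointError(
            "non-finite forces during propagation; offending frame:\n"
            f"q = {state.q!r}"
        )
    state.p -= 0.5 * dt * KCAL_TO_INT * state.grad
    _o_half(state, dt, thermostat_time)
    return state


def _eval_batch(force_provider, Q: np.ndarray):
    """Per-bead (energy, gradient) evaluation, batched when supported."""
    batch = getattr(force_provider, "batch_energy_gradient", None)
    if batch is not None:
        e, g = batch(Q)
        return np.asarray(e, dtype=float), np.asarray(g, dtype=float)
    E = np.empty(Q.shape[0])
    G = np.empty_like(Q)
    for j in range(Q.shape[0]):
        E[j], G[j] = force_provider(Q[j])
    return E, G


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _frame_estimators(state: PIMDState) -> dict:
    """Per-frame potential and kinetic-energy estimator values, kcal/mol."""
    P, ndof = state.P, state.ndof
    beta = 1.0 / (KB * state.T)
    pot = float(np.mean(state.energy))
    # primitive: ndof P/(2β) - (1/P) Σ_j ½ m ω_P² |q_j - q_{j+1}|²
    if P > 1:
        beta_int = 1.0 / (KB_INT * state.T)
        omega_p = P / (beta_int * HBAR_INT)
        dq = state.q - np.roll(state.q, -1, axis=0)
        spring_int = 0.5 * omega_p ** 2 * np.sum(state.masses[None, :] * dq * dq)
        spring = spring_int * INT_TO_KCAL / P
    else:
        spring = 0.0
    ke_prim = ndof * P / (2.0 * beta) - spring
    # centroid virial: ndof/(2β) + (1/2P) Σ_j (q_j - q̄)·∇V(q_j)
    dqc = state.q - state.centroid[None, :]
    ke_vir = ndof / (2.0 * beta) + 0.5 * float(np.sum(dqc * state.grad)) / P
    # extended-system (ring-polymer) Hamiltonian; conserved when unthermostatted
    ham = float(np.sum(state.energy)) \
        + float(np.sum(state.p ** 2 / (2 * state.masses[None, :]))) * INT_TO_KCAL \
        + spring * P
    return {
        "potential": pot,
        "kinetic_primitive": ke_prim,
        "kinetic_virial": ke_vir,
        "total_primitive": pot + ke_prim,
        "total_virial": pot + ke_vir,
        "hamiltonian": ham,
    }


def _block_se(x: np.ndarray, nblocks: int = 20) -> float:
    """Standard error of the mean by block averaging (autocorrelation-aware)."""
    n = len(x)
    nblocks = max(2, min(nblocks, n))
    usable = (n // nblocks) * nblocks
    blocks = x[:usable].reshape(nblocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / math.sqrt(nblocks))


def kinetic_estimators(trajectory: "Trajectory", skip_fraction: float = 0.1):
    """(primitive, virial) quantum kinetic energies with standard errors.

    Averages the per-frame estimator records of a trajectory, discarding the
    initial ``skip_fraction`` as equilibration; errors come from block
    averaging (20 blocks).

    Returns
    -------
    dict with keys 'primitive', 'virial', each (mean, stderr) in kcal/mol.
    """
    rec = trajectory.records
    if rec is None or "kinetic_primitive" not in rec:
        raise ValueError("trajectory carries no estimator records")
    n = len(rec["kinetic_primitive"])
    if n == 0:
        raise ValueError("empty trajectory")
    i0 = int(skip_fraction * n)
    out = {}
    for name, key in (("primitive", "kinetic_primitive"),
                      ("virial", "kinetic_virial")):
        x = np.asarray(rec[key][i0:])
        out[name] = (float(x.mean()), _block_se(x))
    return out


def ring_polymer_covariance(P: int, T: float, mass: float,
                            omega: float) -> np.ndarray:
    """Analytic stationary bead-position covariance on a 1-D harmonic PES.

    For V = ½ m ω² q² the ring-polymer distribution is Gaussian; in normal
    modes ⟨ρ_k²⟩ = kB(PT)/(m(ω² + ω_k²)), so Cov(q) = Cᵀ diag(⟨ρ_k²⟩) C.
    ``omega`` is the physical frequency in fs⁻¹ (from k in internal units:
    ω = sqrt(k_int/m)). Result in Å².
    """
    C, evals = _ring_transform(P)
    beta_int = 1.0 / (KB_INT * T)
    omega_p = P / (beta_int * HBAR_INT)
    omega_k2 = omega_p ** 2 * evals
    var_nm = (KB_INT * P * T) / (mass * (omega ** 2 + omega_k2))
    return C.T @ np.diag(var_nm) @ C


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series produced by :func:`run_trajectory`.

    ``frames`` holds centroid coordinates (n_frames, ndof); ``beads`` the
    bead-resolved positions (n_frames, P, ndof) when requested. ``records``
    are per-frame estimator values. The time grid is uniform:
    t_i = i · dt · stride.
    """

    dt: float
    stride: int
    frames: np.ndarray
    records: dict
    provenance: dict = field(default_factory=dict)
    beads: Optional[np.ndarray] = None
    status: str = "ok"
    final_state: Optional[PIMDState] = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs."""
        return np.arange(self.n_frames) * self.dt * self.stride


def run_trajectory(potential, coords, masses=None, *, T: float = 300.0,
                   P: int = 1, dt: float = 0.2, steps: int = 1000,
                   stride: int = 10, seed: int = 0,
                   thermostat_time: Optional[float] = 100.0,
                   thermal_spread: bool = True,
                   store_beads: bool = False) -> Trajectory:
    """Propagate classical (P=1) or ring-polymer (P>1) Langevin dynamics.

    Parameters mirror the standard protocol for these systems: dt = 0.2 fs
    and T = 300 K by default. ``potential`` is any object with
    ``evaluate(x) -> (energy, gradient)`` (a model surface or a fitted
    force field); ``masses`` defaults to ``potential.masses()``.

    On a non-finite energy/force the run stops and the truncated trajectory
    is returned with ``status='aborted'``.
    """
    if steps < 0 or stride < 1:
        raise ValueError("steps must be >= 0 and stride >= 1")
    if masses is None:
        masses = potential.masses()
    provider = _as_provider(potential)
    state = init_state(coords, masses, T, P, seed,
                       thermal_spread=(thermal_spread and thermostat_time is not None))
    state.energy, state.grad = _eval_batch(provider, state.q)

    frames, beads, recs = [], [], {
        "potential": [], "kinetic_primitive": [], "kinetic_virial": [],
        "total_primitive": [], "total_virial": [], "hamiltonian": [],
    }

    def record():
        frames.append(state.centroid.copy())
        if store_beads:
            beads.append(state.q.copy())
        for k, v in _frame_estimators(state).items():
            recs[k].append(v)

    record()
    status = "ok"
    for istep in range(steps):
        try:
            pimd_step(state, provider, dt, thermostat_time)
        except FloatingPointError:
            status = "aborted"
            break
        if (istep + 1) % stride == 0:
            record()

    return Trajectory(
        dt=dt, stride=stride,
        frames=np.asarray(frames),
        records={k: np.asarray(v) for k, v in recs.items()},
        beads=(np.asarray(beads) if store_beads else None),
        status=status,
        final_state=state,
        provenance={
            "seed": int(seed), "T": float(T), "P": int(P), "dt": float(dt),
            "steps": int(steps), "stride": int(stride),
            "thermostat_time": thermostat_time,
            "potential": getattr(potential, "name", type(potential).__name__),
        },
    )


def bead_convergence_ramp(potential, coords, masses=None, *,
                          ramp=(1, 4, 8, 16, 32), tol=0.01,
                          runner=None, **kwargs):
    """Incrementally increase the bead count until the virial energy settles.

    Runs one trajectory per P in ``ramp`` (default the standard 1→32
    doubling protocol) and declares convergence when the total virial
    energy changes by less than ``tol`` (relative) between successive bead
    counts. Returns (records, P_converged) where records is a list of
    dicts with keys P, energy, stderr; P_converged is None if the ramp
    never settles.

    ``runner`` defaults to :func:`run_trajectory`; pass the compiled
    variant for closed-form surfaces.
    """
    run = runner or run_trajectory
    records = []
    converged = None
    prev = None
    for P in ramp:
        traj = run(potential, coords, masses, P=P, **kwargs)
        est = kinetic_estimators(traj)
        i0 = int(0.1 * traj.n_frames)
        pot_mean = float(np.mean(traj.records["potential"][i0:]))
        energy = est["virial"][0] + pot_mean
        records.append({"P": P, "energy": energy, "stderr": est["virial"][1]})
        if prev is not None and converged is None \
                and abs(energy - prev) <= tol * abs(prev):
            converged = P
        prev = energy
    return records, converged


class _ProviderAdapter:
    def __init__(self, potential):
        self._pot = potential
        batch = getattr(potential, "batch_energy_gradient", None)
        if batch is not None:
            self.batch_energy_gradient = batch

    def __call__(self, x):
        e, g = self._pot.evaluate(x)
        return e, np.asarray(g, dtype=float).reshape(-1)


def _as_provider(potential) -> ForceProvider:
    if callable(potential) and not hasattr(potential, "evaluate"):
        return potential
    return _ProviderAdapter(potential)
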