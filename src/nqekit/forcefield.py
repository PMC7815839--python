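"""Symmetrized gradient-domain force-field regression.

The latent molecular energy E(x) is modelled as a Gaussian process over the
inverse-distance descriptor, and the model is trained directly on forces
F = -∇E. Because the predictor is constructed as the (negative) gradient
field of a single scalar posterior mean, energy conservation holds by
construction, and averaging the kernel over an explicit atom-permutation
group builds permutational invariance in as a prior.

Usage follows the model/results convention::

    model = GDML(dataset, sigma=2.0, lam=1e-10)
    res = model.fit()
    energy, forces = res.predict(config)
    print(res.summary())

The Gram matrix couples every force component of every training geometry:
its dimension is 3N·M for N atoms and M configurations, and training cost
is the cubic solve of that system. A memory guard refuses systems whose
Gram matrix would exceed a configurable budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist

from .data import Dataset, MolecularConfiguration, PermutationGroup
from .descriptors import descriptor_jacobian
from .kernels import _SQRT5

__all__ = ["GDML", "GDMLResults", "select_hyperparameters", "HyperparameterSearch"]


def _permuted_descriptor_jacobian(coords: np.ndarray, perm: np.ndarray):
    """Descriptor of coords[perm] and its Jacobian w.r.t. the *original* coords."""
    n = coords.shape[0]
    d, Jp = descriptor_jacobian(coords[perm])
    J = np.empty_like(Jp)
    for a in range(n):
        J[:, 3 * perm[a]:3 * perm[a] + 3] = Jp[:, 3 * a:3 * a + 3]
    return d, J


class GDML:
    """Gradient-domain force-field model (unfitted).

    Parameters
    ----------
    dataset : Dataset
        Training configurations; every member must carry forces. Energies
        are optional and only set the additive offset of predicted energies.
    sigma : float, optional
        Matérn 5/2 length-scale in descriptor (Å⁻¹) space. Defaults to the
        median pairwise descriptor distance of the training set.
    lam : float
        Ridge regularization added to the Gram diagonal.
    permutations : PermutationGroup, optional
        Physical symmetry prior. Defaults to the identity-only group.
    memory_budget_gb : float
        Refuse to assemble a Gram matrix larger than this.
    """

    def __init__(self, dataset: Dataset, sigma: Optional[float] = None,
                 lam: float = 1e-10, permutations: Optional[PermutationGroup] = None,
                 memory_budget_gb: float = 4.0) -> None:
        if not dataset.has_forces:
            raise ValueError("gradient-domain training requires forces on every "
                             "training configuration")
        if lam < 0:
            raise ValueError(f"regularization must be non-negative, got {lam}")
        self.dataset = dataset
        self.n_atoms = len(dataset.species)
        if self.n_atoms < 2:
            raise ValueError("need at least 2 atoms")
        self.group = permutations or PermutationGroup.identity(self.n_atoms)
        if self.group.n_atoms != self.n_atoms:
            raise ValueError("permutation group size does not match atom count")
        for p in self.group:
            sp = dataset.species
            if tuple(sp[i] for i in p) != tuple(sp):
                raise ValueError(f"permutation {p.tolist()} changes the species list")
        self.lam = float(lam)

        # cache descriptors/Jacobians for every (config, group element)
        M = len(dataset)
        dim = 3 * self.n_atoms * M
        need_gb = (dim ** 2) * 8 / 1e9
        if need_gb > memory_budget_gb:
            raise MemoryError(
                f"Gram matrix would be {dim}x{dim} ({need_gb:.1f} GB) and exceed "
                f"the {memory_budget_gb} GB budget; reduce the training size"
            )
        self._descr = [descriptor_jacobian(c.coordinates)
                       for c in dataset.configurations]
        if sigma is None:
            sigma = self._median_sigma()
        sigma = float(sigma)
        if sigma <= 0:
            raise ValueError(f"kernel length-scale must be positive, got {sigma}")
        self.sigma = sigma

    def _median_sigma(self) -> float:
        D = np.stack([d for d, _ in self._descr])
        if len(D) == 1:
            return 1.0
        dists = pdist(D)
        med = float(np.median(dists))
        return med if med > 0 else 1.0

    # -- Gram assembly -----------------------------------------------------

    def _perm_tables(self, dataset: Dataset):
        """Stacked descriptors/Jacobians of all permuted training geometries."""
        Dg, Jg, owner = [], [], []
        for j, c in enumerate(dataset.configurations):
            for g in self.group:
                d, J = _permuted_descriptor_jacobian(c.coordinates, g)
                Dg.append(d)
                Jg.append(J)
                owner.append(j)
        return np.stack(Dg), np.stack(Jg), np.asarray(owner)

    def _gram(self) -> np.ndarray:
        M = len(self.dataset)
        n3 = 3 * self.n_atoms
        G = len(self.group)
        a = _SQRT5 / self.sigma
        Dg, Jg, owner = self._perm_tables(self.dataset)
        K = np.zeros((M * n3, M * n3))
        for i in range(M):
            Di, Ji = self._descr[i]
            delta = Di[None, :] - Dg                      # (MG, p)
            dist = np.linalg.norm(delta, axis=1)          # (MG,)
            e = np.exp(-a * dist)
            c1 = (a * a / 3.0) * (1.0 + a * dist) * e     # isotropic part
            c2 = (a ** 4 / 3.0) * e                       # rank-one part
            # block_{i,jg} = Jiᵀ (c1 I - c2 δδᵀ) Jg
            dJg = np.einsum("gp,gpx->gx", delta, Jg)      # δᵀ Jg, (MG, 3N)
            for j in range(M):
                acc = np.zeros((n3, n3))
                for g_idx in np.nonzero(owner == j)[0]:
                    acc += c1[g_idx] * (Ji.T @ Jg[g_idx]) \
                        - c2[g_idx] * np.outer(Ji.T @ delta[g_idx], dJg[g_idx])
                K[i * n3:(i + 1) * n3, j * n3:(j + 1) * n3] = acc / G
        return 0.5 * (K + K.T)

    def fit(self) -> "GDMLResults":
        """Solve the regularized force-covariance system and return results."""
        K = self._gram()
        dim = K.shape[0]
        y = self.dataset.forces_array().reshape(dim)
        A = K + self.lam * np.eye(dim)
        jitter_used = 0.0
        try:
            cf = scipy.linalg.cho_factor(A, lower=True)
        except scipy.linalg.LinAlgError:
            if self.lam == 0:
                cond = np.linalg.cond(A)
                raise np.linalg.LinAlgError(
                    f"force-covariance system is singular at lam=0 "
                    f"(condition estimate {cond:.3e}); increase lam"
                ) from None
            jitter_used = 1e-10 * float(np.mean(np.diag(K)))
            warnings.warn(
                f"Cholesky factorization failed; retrying with jitter {jitter_used:.3e}",
                RuntimeWarning, stacklevel=2,
            )
            cf = scipy.linalg.cho_factor(A + jitter_used * np.eye(dim), lower=True)
        alpha = scipy.linalg.cho_solve(cf, y)
        if not np.all(np.isfinite(alpha)):
            raise np.linalg.LinAlgError("non-finite coefficients from solve")
        res = GDMLResults(self, alpha, jitter=jitter_used)
        return res


class GDMLResults:
    """Fitted gradient-domain force field.

    Carries the dual coefficients, the energy offset, and training
    diagnostics; `predict` returns an (energy, forces) pair whose forces
    are the exact analytic negative gradient of the returned energy.
    """

    def __init__(self, model: GDML, alpha: np.ndarray, jitter: float = 0.0) -> None:
        self.model = model
        self.alpha = alpha
        self.jitter = jitter
        self.sigma = model.sigma
        self.lam = model.lam
        n3 = 3 * model.n_atoms
        # precompute permuted tables contracted with coefficients
        Dg, Jg, owner = model._perm_tables(model.dataset)
        self._Dg = Dg
        self._JgA = np.einsum("gpx,gx->gp", Jg, alpha.reshape(-1, n3)[owner])
        self._nG = len(model.group)

        self.offset = 0.0
        ds = model.dataset
        raw = np.array([self._energy_raw(c.coordinates) for c in ds.configurations])
        if ds.has_energies:
            self.offset = float(np.mean(ds.energies_array() - raw))
        # training diagnostics
        F_pred = np.stack([self.predict(c)[1] for c in ds.configurations])
        F_ref = ds.forces_array()
        err = F_pred - F_ref
        self.force_mae = float(np.mean(np.abs(err)))
        self.force_rmse = float(np.sqrt(np.mean(err ** 2)))
        if ds.has_energies:
            E_pred = raw + self.offset
            self.energy_mae = float(np.mean(np.abs(E_pred - ds.energies_array())))
        else:
            self.energy_mae = None

    # -- prediction --------------------------------------------------------

    def _check(self, config: MolecularConfiguration) -> None:
        if config.species != self.model.dataset.species:
            raise ValueError(
                f"species {config.species} do not match the model's "
                f"{self.model.dataset.species}"
            )

    def _kernel_pieces(self, coords: np.ndarray):
        a = _SQRT5 / self.sigma
        d, J = descriptor_jacobian(coords)
        delta = d[None, :] - self._Dg                 # (MG, p)
        dist = np.linalg.norm(delta, axis=1)
        e = np.exp(-a * dist)
        c1 = (a * a / 3.0) * (1.0 + a * dist) * e
        c2 = (a ** 4 / 3.0) * e
        return d, J, delta, c1, c2

    def _energy_raw(self, coords: np.ndarray) -> float:
        _, _, delta, c1, _ = self._kernel_pieces(coords)
        # E = -Σ (∂k/∂x_j)ᵀ α_j = -(1/|G|) Σ c1 δ·(Jg α)
        return float(-np.sum(c1 * np.einsum("gp,gp->g", delta, self._JgA)) / self._nG)

    def predict(self, config: MolecularConfiguration):
        """Energy (kcal/mol) and forces (kcal/mol/Å) for one configuration."""
        self._check(config)
        coords = config.coordinates
        _, J, delta, c1, c2 = self._kernel_pieces(coords)
        proj = np.einsum("gp,gp->g", delta, self._JgA)     # δ·(Jg α)
        energy = float(-np.sum(c1 * proj) / self._nG) + self.offset
        # F = Jᵀ (1/|G|) Σ [c1 (Jg α) - c2 (δ·Jgα) δ]
        vec = (c1[:, None] * self._JgA - (c2 * proj)[:, None] * delta).sum(axis=0)
        forces = (J.T @ vec) / self._nG
        return energy, forces.reshape(-1, 3)

    def predict_forces(self, coords: np.ndarray) -> np.ndarray:
        cfg = MolecularConfiguration(self.model.dataset.species, coords)
        return self.predict(cfg)[1]

    def __call__(self, coords: np.ndarray):
        """(energy, flat gradient) adapter for the dynamics engine."""
        cfg = MolecularConfiguration(self.model.dataset.species,
                                     np.asarray(coords).reshape(-1, 3))
        e, f = self.predict(cfg)
        return e, -f.reshape(-1)

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Gradient-domain force field (Matérn 5/2 on inverse distances)",
            "=" * 62,
            f"atoms                 {self.model.n_atoms}",
            f"training set          {len(ds)} configurations",
            f"symmetry group order  {self._nG}",
            f"sigma                 {self.sigma:.6g}",
            f"lambda                {self.lam:.3g}",
            f"energy offset c       {self.offset:.6f} kcal/mol",
            f"train force MAE       {self.force_mae:.6f} kcal/mol/A",
            f"train force RMSE      {self.force_rmse:.6f} kcal/mol/A",
        ]
        if self.energy_mae is not None:
            lines.append(f"train energy MAE      {self.energy_mae:.6f} kcal/mol")
        if self.jitter:
            lines.append(f"jitter applied        {self.jitter:.3e}")
        return "\n".join(lines)

    def save(self, path) -> None:
        ds = self.model.dataset
        np.savez_compressed(
            path,
            kind="nqekit-gdml-1",
            z=ds.configurations[0].atomic_numbers,
            species=np.array(ds.species),
            R=ds.coordinates_array(),
            F=ds.forces_array(),
            E=(ds.energies_array() if ds.has_energies else np.array([])),
            alpha=self.alpha,
            sigma=self.sigma,
            lam=self.lam,
            offset=self.offset,
            perms=np.stack(list(self.model.group)),
        )

    @classmethod
    def load(cls, path) -> "GDMLResults":
        with np.load(path, allow_pickle=False) as f:
            species = tuple(str(s) for s in f["species"])
            R, F = f["R"], f["F"]
            E = f["E"] if f["E"].size else None
            configs = [
                MolecularConfiguration(species, R[i], None if E is None else E[i], F[i])
                for i in range(len(R))
            ]
            ds = Dataset(configs, provenance={"source": str(path)})
            group = PermutationGroup(list(f["perms"]), len(species))
            model = GDML(ds, sigma=float(f["sigma"]), lam=float(f["lam"]),
                         permutations=group)
            res = cls(model, f["alpha"].copy())
            res.offset = float(f["offset"])
            return res


@dataclass
class HyperparameterSearch:
    sigma: float
    lam: float
    log: list

    def __iter__(self):
        return iter((self.sigma, self.lam))


def select_hyperparameters(dataset: Dataset, sigma_grid: Sequence[float],
                           lam_grid: Sequence[float], split_seed: int,
                           permutations: Optional[PermutationGroup] = None,
                           val_fraction: float = 0.2) -> HyperparameterSearch:
    """Grid search minimizing validation force MAE on a seeded split.

    Ties break toward the smallest sigma, then the smallest lambda. Every
    evaluated candidate is recorded in the returned log.
    """
    sigma_grid = sorted(float(s) for s in sigma_grid)
    lam_grid = sorted(float(l) for l in lam_grid)
    if not sigma_grid or not lam_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    M = len(dataset)
    n_val = max(1, int(round(val_fraction * M)))
    if M - n_val < 1:
        raise ValueError(f"dataset of size {M} too small for a validation split")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(M)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train, val = dataset.subset(train_idx), dataset.subset(val_idx)

    log = []
    best = None
    for s in sigma_grid:
        for l in lam_grid:
            try:
                res = GDML(train, sigma=s, lam=l, permutations=permutations).fit()
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, MemoryError) as exc:
                log.append({"sigma": s, "lam": l, "force_mae": math.inf,
                            "error": str(exc)})
                continue
            errs = [np.abs(res.predict(c)[1] - c.forces).mean()
                    for c in val.configurations]
            mae = float(np.mean(errs))
            log.append({"sigma": s, "lam": l, "force_mae": mae})
            if best is None or mae < best[0] - 1e-15:
                best = (mae, s, l)
    if best is None:
        raise np.linalg.LinAlgError("every hyperparameter candidate failed to train")
    return HyperparameterSearch(sigma=best[1], lam=best[2], log=log)
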