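"""Inverse-distance descriptor for gradient-domain regression.

The descriptor of an N-atom geometry is the vector of inverse interatomic
distances 1/||r_a - r_b|| over all pairs a < b (lexicographic order). It is
invariant under rigid translations and rotations, and an atom permutation
induces a pair permutation of its entries. The Jacobian maps Cartesian
perturbations (3N) to descriptor perturbations (N(N-1)/2) and carries the
chain rule for all kernel derivatives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pair_index", "descriptor", "descriptor_jacobian", "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    """Raised when two atoms (nearly) coincide."""


def pair_index(n_atoms: int) -> np.ndarray:
    """(P, 2) array of atom index pairs (a < b) in descriptor order."""
    a, b = np.triu_indices(n_atoms, k=1)
    return np.column_stack([a, b])


def _diffs_dists(coords: np.ndarray, min_dist: float):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("descriptor requires at least 2 atoms")
    pairs = pair_index(n)
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]   # (P, 3)
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist < min_dist):
        k = int(np.argmin(dist))
        a, b = pairs[k]
        raise DegenerateGeometryError(
            f"atoms {a} and {b} are {dist[k]:.3e} Å apart (< {min_dist} Å); "
            "descriptor is singular for coincident atoms"
        )
    return pairs, diff, dist


def descriptor(coords: np.ndarray, min_dist: float = 1e-8) -> np.ndarray:
    """Inverse pairwise distances, shape (N(N-1)/2,), units Å^-1."""
    _, _, dist = _diffs_dists(coords, min_dist)
    return 1.0 / dist


def descriptor_jacobian(coords: np.ndarray, min_dist: float = 1e-8):
    """Descriptor and its Jacobian d(descriptor)/d(flat coords).

    Returns
    -------
    d : (P,) descriptor
    J : (P, 3N) Jacobian; row for pair (a,b) is -(r_a - r_b)/r^3 in the
        a-block and its negative in the b-block.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    pairs, diff, dist = _diffs_dists(coords, min_dist)
    d = 1.0 / dist
    npairs = len(pairs)
    J = np.zeros((npairs, 3 * n))
    g = -diff / dist[:, None] ** 3                      # d(1/r)/d r_a
    rows = np.arange(npairs)
    for k in range(3):
        J[rows, 3 * pairs[:, 0] + k] = g[:, k]
        J[rows, 3 * pairs[:, 1] + k] = -g[:, k]
    return d, J


def pair_permutation(perm: np.ndarray, n_atoms: int) -> np.ndarray:
    """Pair-index permutation induced by an atom permutation.

    Returns ``pi`` such that descriptor(coords[perm]) == descriptor(coords)[pi].
    """
    perm = np.asarray(perm, dtype=int)
    pairs = pair_index(n_atoms)
    lookup = {}
    for k, (a, b) in enumerate(pairs):
        lookup[(a, b)] = k
    pi = np.empty(len(pairs), dtype=int)
    for k, (a, b) in enumerate(pairs):
        oa, ob = perm[a], perm[b]
        pi[k] = lookup[(min(oa, ob), max(oa, ob))]
    return pi
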