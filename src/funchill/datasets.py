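"""Built-in study layouts and random instance generators.

Everything needed to exercise the package without external files:

* the two-assemblage layout of 20+20 species with 12 shared species
  (:func:`example1_communities`) and the two distance-matrix recipes that
  go with it — one whose within- and cross-assemblage distances share a
  beta(4,4) distribution (:func:`matrix_I`), and one whose non-shared
  cross-assemblage pairs are far (uniform(0.8, 1)) while every other pair
  is close (uniform(0, 0.2)) (:func:`matrix_II`);
* the exact four-species ultrametric / non-ultrametric pair of matrices
  with two completely distinct two-species assemblages
  (:func:`example2_matrices`);
* the block construction used to test the replication principle
  (:func:`replicated_disjoint`);
* seeded random community/distance instances for property tests
  (:func:`random_instance`).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .containers import AbundanceVector, CommunityMatrix, DistanceMatrix
from .errors import ValidationError

__all__ = [
    "example1_communities",
    "matrix_I",
    "matrix_II",
    "example2_matrices",
    "replicated_disjoint",
    "random_instance",
]

_S1 = 28  # pooled richness of the two-assemblage layout


def _species28() -> tuple[str, ...]:
    return tuple(f"sp{i:02d}" for i in range(1, _S1 + 1))


def example1_communities(
    variant: str = "equal", seed: int | None = None
) -> CommunityMatrix:
    """Two assemblages of 20 species each sharing 12 species (28 pooled).

    Assemblage I holds species 1-20, assemblage II species 9-28.  The
    "equal" variant gives every present species relative abundance 1/20.
    The "heterogeneous" variant draws log-normal (sigma = 1) relative
    abundances per assemblage with the given seed.
    """
    sp = _species28()
    z = np.zeros((_S1, 2))
    if variant == "equal":
        z[:20, 0] = 1.0 / 20.0
        z[8:, 1] = 1.0 / 20.0
    elif variant == "heterogeneous":
        rng = np.random.default_rng(seed)
        a1 = rng.lognormal(mean=0.0, sigma=1.0, size=20)
        a2 = rng.lognormal(mean=0.0, sigma=1.0, size=20)
        z[:20, 0] = a1 / a1.sum()
        z[8:, 1] = a2 / a2.sum()
    else:
        raise ValidationError(
            f"unknown variant {variant!r}; expected 'equal' or 'heterogeneous'"
        )
    return CommunityMatrix(sp, ("I", "II"), z)


def _symmetrize_draw(upper: np.ndarray) -> np.ndarray:
    d = np.triu(upper, k=1)
    return d + d.T


def matrix_I(seed: int) -> DistanceMatrix:
    """28×28 distance matrix with every off-diagonal distance drawn from a
    beta(4, 4) distribution, so within- and cross-assemblage distances share
    one distribution and alpha and gamma quadratic entropies are close."""
    rng = np.random.default_rng(seed)
    d = _symmetrize_draw(rng.beta(4.0, 4.0, size=(_S1, _S1)))
    return DistanceMatrix(_species28(), d)


def matrix_II(seed: int) -> DistanceMatrix:
    """28×28 distance matrix in which the pairs between the non-shared
    species of the two assemblages (species 1-8 vs 21-28) are far, drawn
    from uniform(0.8, 1), and every other off-diagonal pair is close,
    drawn from uniform(0, 0.2); gamma quadratic entropy then clearly
    exceeds alpha."""
    rng = np.random.default_rng(seed)
    d = _symmetrize_draw(rng.uniform(0.0, 0.2, size=(_S1, _S1)))
    far = rng.uniform(0.8, 1.0, size=(8, 8))
    d[:8, 20:] = far
    d[20:, :8] = far.T
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(_species28(), d)


def example2_matrices() -> tuple[DistanceMatrix, DistanceMatrix, CommunityMatrix]:
    """The exact four-species desk example: an ultrametric matrix (Case I)
    and a non-ultrametric one (Case II), plus the community of two
    completely distinct assemblages {a, b} and {c, d} with equal abundances.

    Within-assemblage distances are 0.1 (the value forced by the stated
    alpha quadratic entropy of 0.05 under equal abundances); cross distances
    are all 0.2 in Case I, while Case II raises d(a,c) to 0.9 and d(b,d) to
    0.8.
    """
    sp = ("a", "b", "c", "d")
    case1 = np.array(
        [
            [0.0, 0.1, 0.2, 0.2],
            [0.1, 0.0, 0.2, 0.2],
            [0.2, 0.2, 0.0, 0.1],
            [0.2, 0.2, 0.1, 0.0],
        ]
    )
    case2 = case1.copy()
    case2[0, 2] = case2[2, 0] = 0.9
    case2[1, 3] = case2[3, 1] = 0.8
    z = np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 0.5], [0.0, 0.5]])
    Z = CommunityMatrix(sp, ("I", "II"), z)
    return DistanceMatrix(sp, case1), DistanceMatrix(sp, case2), Z


def replicated_disjoint(
    p: AbundanceVector, dm: DistanceMatrix, N: int
) -> tuple[CommunityMatrix, DistanceMatrix]:
    """N relabeled copies of one assemblage with a block distance matrix in
    which every S×S block (within and across copies) equals the base
    matrix, so all within/cross quadratic entropies coincide.  Pooling the
    copies multiplies the functional Hill number and mean functional
    diversity by N and the total functional diversity by N**2."""
    if N < 2:
        raise ValidationError("replication needs N >= 2 copies")
    base = dm.submatrix(p.labels).values
    S = p.n_species
    labels = tuple(
        f"{lab}__rep{k+1}" for k in range(N) for lab in p.labels
    )
    big = np.tile(base, (N, N))
    z = np.zeros((S * N, N))
    for k in range(N):
        z[k * S : (k + 1) * S, k] = p.relative()
    return CommunityMatrix(labels, tuple(f"A{k+1}" for k in range(N)), z), DistanceMatrix(labels, big)


def random_instance(
    S: int, N: int, seed: int, sparsity: float = 0.0
) -> tuple[CommunityMatrix, DistanceMatrix]:
    """Seeded random community and distance matrix for property tests.

    Distances are uniform(0, 1) off the diagonal; abundances are gamma(1)
    draws with each entry zeroed independently with probability
    ``sparsity`` (repaired so every species row and assemblage column keeps
    a positive total)."""
    if S < 2:
        raise ValidationError("random instances need S >= 2 species")
    if not (0.0 <= sparsity < 1.0):
        raise ValidationError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = _symmetrize_draw(rng.uniform(0.0, 1.0, size=(S, S)))
    sp = tuple(f"sp{i:02d}" for i in range(1, S + 1))
    asm = tuple(f"A{k}" for k in range(1, N + 1))
    z = rng.gamma(shape=1.0, scale=1.0, size=(S, N))
    if sparsity > 0:
        z *= rng.random(size=(S, N)) >= sparsity
        for i in range(S):  # keep every species somewhere
            if z[i].sum() == 0:
                z[i, rng.integers(N)] = rng.gamma(1.0)
        for k in range(N):  # keep every assemblage non-empty
            if z[:, k].sum() == 0:
                z[rng.integers(S), k] = rng.gamma(1.0)
    return CommunityMatrix(sp, asm, z), DistanceMatrix(sp, d)
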