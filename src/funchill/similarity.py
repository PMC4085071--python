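"""Normalized functional overlap (similarity) and differentiation measures.

The functional beta diversity FD_beta in [1, N**2] is transformed onto
[0, 1] from four perspectives:

* local distance-overlap C*_qN — the effective proportion of shared species
  pairwise distances in a pair of local assemblages; generalizes Sørensen
  (q=0), Horn (q=1) and Morisita-Horn (q=2);
* regional distance-overlap U*_qN — the shared proportion in the pooled
  assemblage; generalizes Jaccard at q=0, with the same q=1 limit as C*;
* distance-homogeneity S*_qN — linear in 1/FD_beta;
* the complement of the distance-turnover rate, V*_qN — linear in FD_beta.

The abundance-only measures C_qN and U_qN apply the analogous transforms to
the ordinary Hill-number beta in [1, N].  Differentiation is always
1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import CommunityMatrix, DistanceMatrix
from .core import _check_q
from .decompose import fd_beta, hill_partition
from .errors import DomainError

__all__ = [
    "SimilarityProfile",
    "local_overlap",
    "regional_overlap",
    "homogeneity",
    "turnover_complement",
    "abundance_overlap",
    "similarity_profile",
    "FUNCTIONAL_CLASSES",
    "ABUNDANCE_CLASSES",
]

FUNCTIONAL_CLASSES = ("local", "regional", "homogeneity", "turnover")
ABUNDANCE_CLASSES = ("abundance-local", "abundance-regional")

_RANGE_TOL = 1e-9


def _check_fd_beta(fd_beta_value: float, N: int) -> float:
    b = float(fd_beta_value)
    if not (1.0 - _RANGE_TOL <= b <= N**2 * (1.0 + _RANGE_TOL)):
        raise DomainError(
            f"functional beta diversity {b} outside [1, N^2] = [1, {N**2}]; "
            "upstream decomposition is inconsistent"
        )
    return min(max(b, 1.0), float(N**2))


def _check_hill_beta(beta: float, N: int) -> float:
    b = float(beta)
    if not (1.0 - _RANGE_TOL <= b <= N * (1.0 + _RANGE_TOL)):
        raise DomainError(
            f"Hill beta diversity {b} outside [1, N] = [1, {N}]"
        )
    return min(max(b, 1.0), float(N))


def local_overlap(fd_beta_value: float, N: int, q: float) -> float:
    """Local distance-overlap C*_qN, the Sørensen/Horn/Morisita-Horn family
    on functional beta diversity."""
    q = _check_q(q)
    b = _check_fd_beta(fd_beta_value, N)
    if q == 1:
        return 1.0 - np.log(b) / (2.0 * np.log(N))
    e = 1.0 - q
    return float((N ** (2 * e) - b**e) / (N ** (2 * e) - 1.0))


def regional_overlap(fd_beta_value: float, N: int, q: float) -> float:
    """Regional distance-overlap U*_qN, the Jaccard family on functional
    beta diversity; coincides with C*_qN at q = 1."""
    q = _check_q(q)
    b = _check_fd_beta(fd_beta_value, N)
    if q == 1:
        return 1.0 - np.log(b) / (2.0 * np.log(N))
    e = 1.0 - q
    return float(((1.0 / b) ** e - (1.0 / N**2) ** e) / (1.0 - (1.0 / N**2) ** e))


def homogeneity(fd_beta_value: float, N: int) -> float:
    """Distance-homogeneity S*_qN = (1/FD_beta - 1/N^2)/(1 - 1/N^2);
    the functional form of U* at q = 2."""
    b = _check_fd_beta(fd_beta_value, N)
    return float((1.0 / b - 1.0 / N**2) / (1.0 - 1.0 / N**2))


def turnover_complement(fd_beta_value: float, N: int) -> float:
    """One minus the functional distance-turnover rate:
    V*_qN = (N^2 - FD_beta)/(N^2 - 1); the functional form of C* at q = 0."""
    b = _check_fd_beta(fd_beta_value, N)
    return float((N**2 - b) / (N**2 - 1.0))


def abundance_overlap(beta_hill: float, N: int, q: float) -> tuple[float, float]:
    """Abundance-only overlap pair (C_qN, U_qN) from the ordinary
    Hill-number beta in [1, N]."""
    q = _check_q(q)
    b = _check_hill_beta(beta_hill, N)
    if q == 1:
        c = 1.0 - np.log(b) / np.log(N)
        return float(c), float(c)
    e = 1.0 - q
    C = (N**e - b**e) / (N**e - 1.0)
    U = (b**-e - N**-e) / (1.0 - N**-e)
    return float(C), float(U)


def _functional_similarity(b: float, N: int, q: float, kind: str) -> float:
    if kind == "local":
        return local_overlap(b, N, q)
    if kind == "regional":
        return regional_overlap(b, N, q)
    if kind == "homogeneity":
        return homogeneity(b, N)
    if kind == "turnover":
        return turnover_complement(b, N)
    raise DomainError(
        f"unknown similarity class {kind!r}; expected one of "
        f"{FUNCTIONAL_CLASSES + ABUNDANCE_CLASSES}"
    )


@dataclass(frozen=True)
class SimilarityProfile:
    """Values of one overlap class over a q grid for one assemblage set
    (``pair`` is None for all-N profiles, or the pair of assemblage labels
    in pairwise mode).  ``differentiation`` is 1 - similarity."""

    kind: str
    q: tuple[float, ...]
    similarity: tuple[float, ...]
    pair: tuple[str, str] | None = None

    @property
    def differentiation(self) -> tuple[float, ...]:
        return tuple(1.0 - s for s in self.similarity)


def _profile_for(
    Z: CommunityMatrix,
    dm: DistanceMatrix | None,
    q_grid: Sequence[float],
    kind: str,
    scheme: str,
    pair: tuple[str, str] | None,
) -> SimilarityProfile:
    N = Z.n_assemblages
    values = []
    for q in q_grid:
        if kind in ABUNDANCE_CLASSES:
            beta = hill_partition(Z, q, scheme).beta
            C, U = abundance_overlap(beta, N, q)
            values.append(C if kind == "abundance-local" else U)
        else:
            b = fd_beta(Z, dm, q, scheme).beta
            values.append(_functional_similarity(b, N, q, kind))
    return SimilarityProfile(
        kind=kind, q=tuple(float(q) for q in q_grid),
        similarity=tuple(values), pair=pair,
    )


def similarity_profile(
    Z: CommunityMatrix,
    dm: DistanceMatrix | None,
    q_grid: Sequence[float],
    kind: str = "local",
    scheme: str = "relative",
    pairwise: bool = False,
) -> list[SimilarityProfile]:
    """Overlap profile(s) of one class over a q grid.

    With ``pairwise=True`` every unordered pair of assemblages is profiled
    separately (N = 2 each); otherwise one profile over all N assemblages is
    returned.  ``dm`` may be None for the abundance-only classes.
    """
    if kind in FUNCTIONAL_CLASSES and dm is None:
        raise DomainError(f"class {kind!r} requires a distance matrix")
    if kind not in FUNCTIONAL_CLASSES + ABUNDANCE_CLASSES:
        raise DomainError(f"unknown similarity class {kind!r}")
    q_grid = [_check_q(q) for q in q_grid]
    if not pairwise:
        return [_profile_for(Z, dm, q_grid, kind, scheme, None)]
    out = []
    names = Z.assemblages
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sub = CommunityMatrix(
                Z.species, (names[a], names[b]), Z.z[:, [a, b]]
            )
            out.append(
                _profile_for(sub, dm, q_grid, kind, scheme, (names[a], names[b]))
            )
    return out
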