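"""Single-assemblage and assemblage-pair diversity measures.

The central quantities are Hill numbers and their distance-based
generalization.  For an assemblage with relative abundances p_i and a
symmetric pairwise distance matrix [d_ij], Rao's quadratic entropy

    Q = sum_ij d_ij p_i p_j

is the mean distance between two randomly sampled individuals.  The
functional Hill number of order q,

    qD(Q) = [ sum_ij (d_ij / Q) (p_i p_j)^q ] ** (1 / (2 (1 - q))),

is the effective number of equally abundant, equally distinct species with
constant pairwise distance Q.  Two derived measures carry distance units:
the mean functional diversity MD = Q * D and the total functional diversity
FD = Q * D**2.  At q = 0, FD reduces to FAD, the plain sum of pairwise
distances between the species present; with equal abundances FD = FAD for
every q; with a constant distance matrix D reduces to the ordinary Hill
number.

All sums run over the full S^2 ordered species pairs, diagonal included, so
nonzero intraspecific distances are honoured if supplied.  Pairs with zero
joint abundance contribute nothing for q > 0 and are excluded at q = 0
(presence requires positive abundance); 0 * log 0 := 0.  The q = 1 case
dispatches exactly to the closed-form limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import (
    AbundanceVector,
    CommunityMatrix,
    DistanceMatrix,
    align_distance,
    restrict_to_distance,
)
from .errors import DegenerateDistanceError, DomainError, ValidationError

__all__ = [
    "FunctionalTriple",
    "CrossAssemblagePair",
    "LegacyResult",
    "hill_number",
    "quadratic_entropy",
    "fad",
    "functional_hill_number",
    "functional_triple",
    "weighted_gini_simpson",
    "max_distance_effective_number",
    "cross_pair_measures",
    "legacy_differentiation",
    "diversity_profile",
]


def _as_abundance(p) -> AbundanceVector:
    if isinstance(p, AbundanceVector):
        return p
    raise TypeError(f"expected AbundanceVector, got {type(p).__name__}")


def _check_q(q: float) -> float:
    q = float(q)
    if not np.isfinite(q) or q < 0:
        raise DomainError(f"diversity order q must be a nonnegative real, got {q}")
    return q


def hill_number(p: AbundanceVector | Sequence[float], q: float) -> float:
    """Hill number (effective number of species) of order q.

    q = 0 gives species richness, q = 1 the exponential of Shannon entropy,
    q = 2 the inverse Simpson concentration.  ``p`` may be an
    :class:`AbundanceVector` or a plain abundance sequence.
    """
    q = _check_q(q)
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(tuple(f"s{i}" for i in range(len(p))), np.asarray(p))
    rel = p.relative()
    rel = rel[rel > 0]
    if q == 1:
        return float(np.exp(-np.sum(rel * np.log(rel))))
    return float(np.sum(rel**q) ** (1.0 / (1.0 - q)))


def _aligned_rel(p: AbundanceVector, dm: DistanceMatrix):
    """Relative abundances and the matching distance submatrix."""
    d = align_distance(dm, p.labels)
    return p.relative(), d


def quadratic_entropy(p: AbundanceVector, dm: DistanceMatrix) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j (distance units)."""
    rel, d = _aligned_rel(_as_abundance(p), dm)
    return float(rel @ d @ rel)


def fad(dm: DistanceMatrix, present: Sequence[str] | None = None) -> float:
    """Functional attribute diversity: the sum of pairwise distances over all
    ordered species pairs (each unordered pair counted twice, diagonal
    included)."""
    if present is None:
        d = dm.values
    else:
        d = align_distance(dm, tuple(present))
    return float(d.sum())


def _joint_power_sum(d: np.ndarray, pp: np.ndarray, Q: float, q: float) -> float:
    """sum over pairs with positive joint abundance of (d/Q) * pp**q."""
    mask = pp > 0
    if q == 0:
        return float(d[mask].sum() / Q)
    return float(np.sum((d[mask] / Q) * pp[mask] ** q))


def _functional_D_from_joint(d: np.ndarray, pp: np.ndarray, q: float) -> float:
    """Functional Hill number from a joint-abundance matrix pp (summing to
    one) and its matching distance matrix d."""
    Q = float(np.sum(d * pp))
    if Q <= 0:
        n_pos = int(np.count_nonzero(pp.sum(axis=1) > 0))
        if n_pos <= 1:
            warnings.warn(
                "single species with zero intraspecific distance: Q = 0, "
                "returning D = 1 by convention",
                stacklevel=3,
            )
            return 1.0
        raise DegenerateDistanceError(
            "quadratic entropy is zero with more than one species present; "
            "functional measures are undefined"
        )
    if q == 1:
        mask = pp > 0
        ent = np.sum((d[mask] / Q) * pp[mask] * np.log(pp[mask]))
        return float(np.exp(-0.5 * ent))
    s = _joint_power_sum(d, pp, Q, q)
    return float(s ** (1.0 / (2.0 * (1.0 - q))))


def functional_hill_number(
    p: AbundanceVector, dm: DistanceMatrix, q: float
) -> float:
    """Functional Hill number qD(Q): the effective number of equally abundant
    and equally distinct species with constant pairwise distance Q."""
    q = _check_q(q)
    rel, d = _aligned_rel(_as_abundance(p), dm)
    return _functional_D_from_joint(d, np.outer(rel, rel), q)


@dataclass(frozen=True)
class FunctionalTriple:
    """Per-assemblage functional diversity at one order q.

    Q is the quadratic entropy (distance units), D the functional Hill
    number (effective species), MD = Q*D the mean functional diversity and
    FD = Q*D**2 the total functional diversity (both in distance units).
    """

    q: float
    Q: float
    D: float
    MD: float
    FD: float


def functional_triple(
    p: AbundanceVector, dm: DistanceMatrix, q: float
) -> FunctionalTriple:
    """Quadratic entropy, functional Hill number, mean and total functional
    diversity of one assemblage at order q."""
    q = _check_q(q)
    rel, d = _aligned_rel(_as_abundance(p), dm)
    Q = float(rel @ d @ rel)
    D = _functional_D_from_joint(d, np.outer(rel, rel), q)
    return FunctionalTriple(q=q, Q=Q, D=D, MD=Q * D, FD=Q * D * D)


def weighted_gini_simpson(p: AbundanceVector, dm: DistanceMatrix) -> float:
    """Distance-weighted Gini-Simpson index
    GS_D = sum_ij d_ij p_i p_j (1 - p_i p_j).

    Satisfies 2FD(Q) = Q**2 / (Q - GS_D) when Q > GS_D.
    """
    rel, d = _aligned_rel(_as_abundance(p), dm)
    pp = np.outer(rel, rel)
    return float(np.sum(d * pp * (1.0 - pp)))


def max_distance_effective_number(Q: float, d_max: float) -> float:
    """Effective number of equally distinct species with maximum distance:
    De = 1 / (1 - Q/d_max).  Undefined for Q >= d_max."""
    Q = float(Q)
    d_max = float(d_max)
    if Q < 0:
        raise DomainError(f"quadratic entropy must be nonnegative, got {Q}")
    if Q == 0:
        return 1.0
    if d_max <= 0 or Q >= d_max:
        raise DomainError(
            f"effective number with maximum distance undefined for "
            f"Q = {Q} >= d_max = {d_max}"
        )
    return 1.0 / (1.0 - Q / d_max)


@dataclass(frozen=True)
class CrossAssemblagePair:
    """Cross-assemblage functional quantities for a pair of assemblages.

    Q_km is the abundance-weighted mean distance between a species of the
    first and a species of the second assemblage; FAD_km the plain sum of
    those cross distances over species present in each.
    """

    q: float
    Q_km: float
    FAD_km: float
    D_pair: float
    MD_pair: float
    FD_pair: float


def cross_pair_measures(
    p1: AbundanceVector, p2: AbundanceVector, dm: DistanceMatrix, q: float
) -> CrossAssemblagePair:
    """Functional diversity of a pair of assemblages: effective numbers of
    equally abundant, equally distinct species in each assemblage with
    constant cross distance Q_12; FD_pair = Q_12 * D_pair**2 and reduces to
    FAD_12 at q = 0."""
    q = _check_q(q)
    p1, p2 = _as_abundance(p1), _as_abundance(p2)
    pos = {lab: i for i, lab in enumerate(dm.labels)}
    missing = [x for x in (*p1.labels, *p2.labels) if x not in pos]
    if missing:
        from .errors import AlignmentError

        raise AlignmentError(
            f"species not in distance matrix: {sorted(set(missing))}",
            tuple(sorted(set(missing))),
        )
    i1 = np.array([pos[x] for x in p1.labels])
    i2 = np.array([pos[x] for x in p2.labels])
    dcross = dm.values[np.ix_(i1, i2)]
    r1, r2 = p1.relative(), p2.relative()
    pp = np.outer(r1, r2)
    Q12 = float(np.sum(dcross * pp))
    mask = pp > 0
    FAD12 = float(dcross[mask].sum())
    if Q12 <= 0:
        raise DegenerateDistanceError(
            "cross-assemblage quadratic entropy is zero; pair measures undefined"
        )
    if q == 1:
        ent = np.sum((dcross[mask] / Q12) * pp[mask] * np.log(pp[mask]))
        D = float(np.exp(-0.5 * ent))
    elif q == 0:
        D = float(np.sqrt(FAD12 / Q12))
    else:
        s = float(np.sum((dcross[mask] / Q12) * pp[mask] ** q))
        D = float(s ** (1.0 / (2.0 * (1.0 - q))))
    return CrossAssemblagePair(
        q=q, Q_km=Q12, FAD_km=FAD12, D_pair=D, MD_pair=Q12 * D, FD_pair=Q12 * D * D
    )


@dataclass(frozen=True)
class LegacyResult:
    """Quadratic-entropy-based diversities and the three legacy
    differentiation measures the functional framework is compared against."""

    Q_gamma: float
    Q_alpha: float
    d_max: float
    De_gamma: float
    De_alpha: float
    GS_D: float
    diff_additive: float
    diff_debello: float
    diff_villeger: float


def legacy_differentiation(
    Z: CommunityMatrix, dm: DistanceMatrix, d_max_scope: str = "pooled"
) -> LegacyResult:
    """Quadratic-entropy differentiation measures over N assemblages.

    Uses equal-weight pooling of relative abundances.  ``diff_additive`` is
    the quadratic-entropy excess normalized by the gamma quadratic entropy.
    The other two transform Q to the effective number of species with
    maximum distance, De = 1/(1 - Q/d_max), then normalize the resulting
    multiplicative beta:

        diff_debello  = (1 - alpha_e/gamma_e) / (1 - 1/N)
        diff_villeger = (gamma_e/alpha_e - 1) / (N - 1)

    ``d_max_scope`` selects the maximum distance: "pooled" (default) takes
    the maximum over the distance matrix restricted to species present in
    ``Z``; "matrix" takes the maximum of the full supplied matrix.
    """
    if Z.n_assemblages < 2:
        raise ValidationError("legacy differentiation needs at least 2 assemblages")
    if d_max_scope not in ("pooled", "matrix"):
        raise DomainError(f"unknown d_max scope {d_max_scope!r}")
    Z, d = restrict_to_distance(Z, dm)
    rel = Z.z / Z.z.sum(axis=0, keepdims=True)  # equal-weight pooling
    pooled = rel.mean(axis=1)
    Q_gamma = float(pooled @ d @ pooled)
    Q_within = [float(rel[:, k] @ d @ rel[:, k]) for k in range(Z.n_assemblages)]
    Q_alpha = float(np.mean(Q_within))
    d_max = float(d.max()) if d_max_scope == "pooled" else dm.d_max
    if Q_gamma <= 0:
        raise DegenerateDistanceError("gamma quadratic entropy is zero")
    pooled_av = AbundanceVector(Z.species, pooled)
    gs = weighted_gini_simpson(pooled_av, DistanceMatrix(Z.species, d))
    De_gamma = max_distance_effective_number(Q_gamma, d_max)
    De_alpha = max_distance_effective_number(Q_alpha, d_max)
    N = Z.n_assemblages
    diff_additive = (Q_gamma - Q_alpha) / Q_gamma
    diff_debello = (1.0 - De_alpha / De_gamma) / (1.0 - 1.0 / N)
    diff_villeger = (De_gamma / De_alpha - 1.0) / (N - 1.0)
    return LegacyResult(
        Q_gamma=Q_gamma,
        Q_alpha=Q_alpha,
        d_max=d_max,
        De_gamma=De_gamma,
        De_alpha=De_alpha,
        GS_D=gs,
        diff_additive=diff_additive,
        diff_debello=diff_debello,
        diff_villeger=diff_villeger,
    )


def diversity_profile(
    p: AbundanceVector, dm: DistanceMatrix, q_grid: Sequence[float]
) -> list[FunctionalTriple]:
    """Functional diversity triple at each order of a nonnegative q grid."""
    q_grid = [_check_q(q) for q in q_grid]
    return [functional_triple(p, dm, q) for q in q_grid]
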