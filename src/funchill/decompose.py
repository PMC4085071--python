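"""Gamma/alpha/beta partitioning of functional diversity and Hill numbers.

Gamma diversity is computed from the species relative abundances of the
pooled assemblage; alpha is the effective diversity per assemblage (for
total functional diversity: per *pair* of assemblages); beta = gamma/alpha.
For the total functional diversity FD the beta component lies in [1, N**2]
and equals N**2 exactly when the N assemblages share no species; for the
functional Hill number D and the mean functional diversity MD the beta
components coincide and equal sqrt(FD_beta), lying in [1, N].

Two pooling schemes are supported.  Under the "relative" scheme (default,
used by every worked example) each assemblage column is first rescaled to
sum to one, so assemblages enter with equal weight and the pooled total
z_++ equals N.  Under the "absolute" scheme raw abundances are pooled, so
larger assemblages weigh more.  In the alpha formulas Q always refers to
the quadratic entropy of the *pooled* assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AbundanceVector, CommunityMatrix, restrict_to_distance
from .core import _check_q, functional_triple, hill_number
from .errors import DegenerateDistanceError, DomainError, ValidationError

__all__ = [
    "PoolingScheme",
    "DecompositionResult",
    "pool",
    "fd_gamma",
    "fd_alpha",
    "fd_beta",
    "hill_partition",
    "functional_evenness",
]

SCHEMES = ("absolute", "relative")


def _scheme_z(Z: CommunityMatrix, scheme: str) -> np.ndarray:
    if scheme not in SCHEMES:
        raise DomainError(f"pooling scheme must be one of {SCHEMES}, got {scheme!r}")
    z = Z.z
    if scheme == "relative":
        z = z / z.sum(axis=0, keepdims=True)
    return z


def pool(Z: CommunityMatrix, scheme: str = "relative") -> AbundanceVector:
    """Pooled relative abundances z_i+/z_++ under the given scheme."""
    z = _scheme_z(Z, scheme)
    tot = z.sum(axis=1)
    return AbundanceVector(Z.species, tot / tot.sum())


@dataclass(frozen=True)
class DecompositionResult:
    """Gamma/alpha/beta of one measure at one order under one scheme.

    For functional measures ``Q_pooled`` is the quadratic entropy of the
    pooled assemblage; ``D_beta``/``MD_beta`` (= sqrt(FD beta)) accompany an
    FD decomposition.
    """

    measure: str
    q: float
    scheme: str
    gamma: float
    alpha: float
    beta: float
    n_assemblages: int
    Q_pooled: float | None = None
    D_beta: float | None = None
    MD_beta: float | None = None


def _pooled_Q(Z: CommunityMatrix, d: np.ndarray, scheme: str) -> tuple[np.ndarray, float]:
    z = _scheme_z(Z, scheme)
    a = z / z.sum()  # z_ik / z_++
    s = a.sum(axis=1)  # z_i+ / z_++
    Q = float(s @ d @ s)
    if Q <= 0:
        if Z.n_species > 1:
            raise DegenerateDistanceError(
                "pooled quadratic entropy is zero with more than one species"
            )
        raise DegenerateDistanceError(
            "pooled quadratic entropy is zero; functional decomposition undefined"
        )
    return a, Q


def fd_gamma(Z: CommunityMatrix, dm, q: float, scheme: str = "relative") -> float:
    """Functional gamma diversity: total functional diversity of the pooled
    assemblage."""
    q = _check_q(q)
    Z, d = restrict_to_distance(Z, dm)
    a, Q = _pooled_Q(Z, d, scheme)
    pooled = AbundanceVector(Z.species, a.sum(axis=1))
    from .containers import DistanceMatrix

    return functional_triple(pooled, DistanceMatrix(Z.species, d), q).FD


def fd_alpha(Z: CommunityMatrix, dm, q: float, scheme: str = "relative") -> float:
    """Functional alpha diversity: the effective total distance between
    species of a pair of individual assemblages,

        (Q/N^2) * [ sum_ij (d_ij/Q) sum_km (z_ik z_jm / z_++^2)^q ]^(1/(1-q)),

    with Q the *pooled* quadratic entropy.  At q = 0 this is the average FAD
    per assemblage pair.  The double assemblage sum factorizes over k and m,
    so the computation is O(S^2 + S N).
    """
    q = _check_q(q)
    Z, d = restrict_to_distance(Z, dm)
    a, Q = _pooled_Q(Z, d, scheme)
    N = Z.n_assemblages
    if q == 1:
        s = a.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), 0.0)
        h = (a * la).sum(axis=1)  # sum_k a_ik ln a_ik
        # sum_km a_ik a_jm ln(a_ik a_jm) = h_i s_j + s_i h_j
        ent = float(np.sum((d / Q) * (np.outer(h, s) + np.outer(s, h))))
        return (Q / N**2) * float(np.exp(-ent))
    if q == 0:
        t = (a > 0).sum(axis=1).astype(float)  # number of assemblages holding i
    else:
        t = np.where(a > 0, a, 0.0) ** q
        t = t.sum(axis=1)
    inner = float(t @ (d / Q) @ t)
    return (Q / N**2) * inner ** (1.0 / (1.0 - q))


def fd_beta(
    Z: CommunityMatrix, dm, q: float, scheme: str = "relative"
) -> DecompositionResult:
    """Multiplicative functional beta diversity FD_beta = gamma/alpha,
    the effective number of equally large, completely distinct assemblage
    pairs, in [1, N**2].  Also reports D_beta = MD_beta = sqrt(FD_beta)."""
    q = _check_q(q)
    Zr, d = restrict_to_distance(Z, dm)
    _, Q = _pooled_Q(Zr, d, scheme)
    gamma = fd_gamma(Z, dm, q, scheme)
    alpha = fd_alpha(Z, dm, q, scheme)
    beta = gamma / alpha
    root = float(np.sqrt(beta))
    return DecompositionResult(
        measure="FD",
        q=q,
        scheme=scheme,
        gamma=gamma,
        alpha=alpha,
        beta=beta,
        n_assemblages=Z.n_assemblages,
        Q_pooled=Q,
        D_beta=root,
        MD_beta=root,
    )


def hill_partition(
    Z: CommunityMatrix, q: float, scheme: str = "relative"
) -> DecompositionResult:
    """Abundance-only partition of Hill numbers over N assemblages.

    gamma is the Hill number of the pooled relative abundances; alpha is the
    effective number of species per assemblage,

        alpha = (1/N) [ sum_ik (z_ik / z_++)^q ]^(1/(1-q)),

    giving beta = gamma/alpha in [1, N] for every q >= 0 and any abundance
    type.
    """
    q = _check_q(q)
    if Z.n_assemblages < 2:
        raise ValidationError("partitioning needs at least 2 assemblages")
    z = _scheme_z(Z, scheme)
    a = z / z.sum()
    N = Z.n_assemblages
    gamma = hill_number(AbundanceVector(Z.species, a.sum(axis=1)), q)
    pos = a[a > 0]
    if q == 1:
        alpha = float(np.exp(-np.sum(pos * np.log(pos)))) / N
    else:
        alpha = float(np.sum(pos**q) ** (1.0 / (1.0 - q))) / N
    return DecompositionResult(
        measure="Hill",
        q=q,
        scheme=scheme,
        gamma=gamma,
        alpha=alpha,
        beta=gamma / alpha,
        n_assemblages=N,
    )


def functional_evenness(
    p: AbundanceVector, dm, q: float
) -> tuple[float | None, float | None]:
    """Functional evenness ratios qFD/0FD and log(qFD)/log(0FD) for q > 0.

    Returns (None, None) for a single species (FD degenerate) and a None
    log-ratio when 0FD <= 1.
    """
    q = _check_q(q)
    if q <= 0:
        raise DomainError("functional evenness is defined for q > 0")
    fd0 = functional_triple(p, dm, 0.0).FD
    fdq = functional_triple(p, dm, q).FD
    if fd0 <= 0:
        return None, None
    ratio = fdq / fd0
    log_ratio = None if fd0 <= 1.0 else float(np.log(fdq) / np.log(fd0))
    return float(ratio), log_ratio
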