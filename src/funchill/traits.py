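"""Trait tables, Gower mixed-variable distances and matrix diagnostics.

The Gower coefficient handles mixed quantitative and categorical traits:
each quantitative trait contributes |x_i - x_j| / range, each categorical
or binary trait contributes 0/1 mismatch, and the per-pair average is taken
over jointly observed traits (pairwise deletion of missing values), with
optional trait weights.  The result is a symmetric distance matrix in
[0, 1] with zero diagonal.  Trait-derived matrices are generally
non-ultrametric, which is why :func:`is_ultrametric` is provided as a
diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, _check_labels
from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["TraitTable", "gower_matrix", "is_ultrametric"]

TRAIT_TYPES = ("quantitative", "categorical", "binary", "ordinal")


@dataclass(frozen=True)
class TraitTable:
    """Species × trait table with per-column types.

    ``types`` maps each trait column to "quantitative", "categorical" or
    "binary".  "ordinal" is accepted but treated as categorical with a
    warning (ranks are not interpolated).  Missing values (NaN) are allowed.
    """

    table: pd.DataFrame
    types: Mapping[str, str]

    def __post_init__(self):
        _check_labels(self.table.index, "species")
        if self.table.shape[1] < 1:
            raise ValidationError("trait table needs at least one trait column")
        unknown = [c for c in self.table.columns if c not in self.types]
        if unknown:
            raise ValidationError(f"no type declared for traits: {unknown}")
        bad = {c: t for c, t in self.types.items()
               if c in self.table.columns and t not in TRAIT_TYPES}
        if bad:
            raise ValidationError(
                f"unknown trait types {bad}; expected one of {TRAIT_TYPES}"
            )
        for c, t in self.types.items():
            if c in self.table.columns and t == "quantitative":
                vals = pd.to_numeric(self.table[c], errors="coerce")
                if vals.notna().sum() and not np.isfinite(vals.dropna()).all():
                    raise ValidationError(f"non-finite values in quantitative trait {c!r}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(str(x) for x in self.table.index)


def gower_matrix(
    tt: TraitTable, weights: Mapping[str, float] | None = None
) -> DistanceMatrix:
    """Gower distance matrix from a mixed-type trait table.

    Weights default to equal.  A quantitative trait with zero range across
    the table is dropped with a warning.  A species pair with no jointly
    observed traits is an error naming the pair.
    """
    df = tt.table
    species = tt.species
    S = len(species)
    num = np.zeros((S, S))
    den = np.zeros((S, S))
    used_any = False
    for col in df.columns:
        ttype = tt.types[col]
        if ttype == "ordinal":
            logger.warning(
                "trait %r declared ordinal; treated as categorical", col
            )
            ttype = "categorical"
        w = 1.0 if weights is None else float(weights.get(col, 0.0))
        if w < 0:
            raise DomainError(f"negative weight for trait {col!r}")
        if w == 0 and weights is not None:
            continue
        if ttype == "quantitative":
            x = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            obs = np.isfinite(x)
            rng = (np.nanmax(x) - np.nanmin(x)) if obs.any() else 0.0
            if rng <= 0:
                logger.warning(
                    "quantitative trait %r has zero range; dropped", col
                )
                continue
            delta = np.abs(x[:, None] - x[None, :]) / rng
        else:  # categorical / binary: 0-1 mismatch
            x = df[col].to_numpy(dtype=object)
            obs = np.array([v is not None and v == v for v in x])  # NaN-safe
            eq = np.array(
                [[a == b for b in x] for a in x], dtype=bool
            )
            delta = np.where(eq, 0.0, 1.0)
        both = np.outer(obs, obs)
        num += np.where(both, w * np.nan_to_num(delta), 0.0)
        den += np.where(both, w, 0.0)
        used_any = True
    if not used_any:
        raise ValidationError("no usable trait columns after dropping")
    np.fill_diagonal(den, np.where(np.diag(den) > 0, np.diag(den), 1.0))
    uncovered = np.argwhere((den <= 0) & ~np.eye(S, dtype=bool))
    if uncovered.size:
        i, j = uncovered[0]
        raise ValidationError(
            f"species pair ({species[i]!r}, {species[j]!r}) has no jointly "
            "observed traits"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(species, d)


def is_ultrametric(
    dm: DistanceMatrix, tol: float = 1e-9, max_violations: int = 10
) -> tuple[bool, list[tuple[str, str, str]]]:
    """Check the ultrametric criterion d(x,y) <= max{d(x,z), d(y,z)}.

    Returns (True, []) if every species triple satisfies the criterion
    within ``tol``, otherwise (False, up to ``max_violations`` offending
    (x, y, z) triples) for diagnostics.
    """
    d = dm.values
    S = dm.n_species
    violations: list[tuple[str, str, str]] = []
    for k in range(S):
        # max(d_ik, d_jk) for all pairs (i, j)
        m = np.maximum(d[:, k][:, None], d[:, k][None, :])
        bad = np.argwhere(d > m + tol)
        for i, j in bad:
            if i < j and i != k and j != k:
                violations.append((dm.labels[i], dm.labels[j], dm.labels[k]))
                if len(violations) >= max_violations:
                    return False, violations
    return (len(violations) == 0), violations
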