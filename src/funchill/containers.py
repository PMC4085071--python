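"""Labelled containers for distance matrices and community abundance data.

These are thin, validated wrappers around NumPy arrays.  All species
matching anywhere in the package is by label, never by position; the
containers therefore carry ordered label tuples and provide re-indexing
helpers used by the measure functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance for the symmetry check of distance matrices
SYMMETRY_RTOL = 1e-10


def _check_labels(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what} labels: {dupes}")
    return labels


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative S×S matrix of pairwise functional distances.

    The diagonal holds intraspecific distances (zero unless the data say
    otherwise); it is carried through every sum in the package.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(self.labels, "species"))
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"distance matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels but matrix of shape {v.shape}"
            )
        if v.shape[0] < 1:
            raise ValidationError("distance matrix needs at least one species")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix contains non-finite entries")
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValidationError(
                f"negative distance at ({self.labels[i]}, {self.labels[j]})"
            )
        scale = max(np.abs(v).max(), 1.0)
        bad = np.argwhere(np.abs(v - v.T) > SYMMETRY_RTOL * scale)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"asymmetric distances at ({self.labels[i]}, {self.labels[j]}): "
                f"{v[i, j]!r} vs {v[j, i]!r}"
            )
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    @property
    def n_species(self) -> int:
        return len(self.labels)

    @property
    def d_max(self) -> float:
        """Maximum entry of the matrix."""
        return float(self.values.max())

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Re-index to ``labels`` (order preserved); unknown labels raise."""
        labels = tuple(labels)
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = tuple(lab for lab in labels if lab not in pos)
        if missing:
            raise AlignmentError(
                f"species not in distance matrix: {list(missing)}", missing
            )
        idx = np.array([pos[lab] for lab in labels], dtype=int)
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValidationError(
                "distance table row labels must equal column labels in order"
            )
        return cls(tuple(str(x) for x in df.index), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class AbundanceVector:
    """Species abundances of a single assemblage (counts, biomass, cover or
    relative abundances)."""

    labels: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(self.labels, "species"))
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 1 or a.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels but abundance array of shape {a.shape}"
            )
        if not np.all(np.isfinite(a)):
            raise ValidationError("abundances contain non-finite values")
        if np.any(a < 0):
            bad = self.labels[int(np.argwhere(a < 0)[0][0])]
            raise ValidationError(f"negative abundance for species {bad!r}")
        if a.sum() <= 0:
            raise ValidationError("at least one abundance must be positive")
        object.__setattr__(self, "abundances", a)

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def relative(self) -> np.ndarray:
        """Relative abundances summing to one."""
        return self.abundances / self.abundances.sum()

    def present(self) -> tuple[str, ...]:
        """Labels of species with positive abundance."""
        return tuple(
            lab for lab, a in zip(self.labels, self.abundances) if a > 0
        )

    def drop_absent(self) -> "AbundanceVector":
        keep = self.abundances > 0
        return AbundanceVector(
            tuple(np.array(self.labels, dtype=object)[keep]), self.abundances[keep]
        )

    @classmethod
    def from_series(cls, s: pd.Series) -> "AbundanceVector":
        return cls(tuple(str(x) for x in s.index), s.to_numpy(dtype=float))


@dataclass(frozen=True)
class CommunityMatrix:
    """Species × assemblage abundance table (z_ik).

    Rows are species, columns are assemblages.  Species rows with zero total
    abundance are dropped at construction (with a logged warning); every
    assemblage column must have positive total.
    """

    species: tuple[str, ...]
    assemblages: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "species", _check_labels(self.species, "species"))
        object.__setattr__(
            self, "assemblages", _check_labels(self.assemblages, "assemblage")
        )
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape != (len(self.species), len(self.assemblages)):
            raise ValidationError(
                f"abundance array of shape {z.shape} does not match "
                f"{len(self.species)} species × {len(self.assemblages)} assemblages"
            )
        if not np.all(np.isfinite(z)):
            raise ValidationError("community matrix contains non-finite values")
        if np.any(z < 0):
            i, k = np.argwhere(z < 0)[0]
            raise ValidationError(
                f"negative abundance for species {self.species[i]!r} in "
                f"assemblage {self.assemblages[k]!r}"
            )
        col = z.sum(axis=0)
        if np.any(col <= 0):
            k = int(np.argwhere(col <= 0)[0][0])
            raise ValidationError(
                f"assemblage {self.assemblages[k]!r} has zero total abundance"
            )
        row = z.sum(axis=1)
        if np.any(row <= 0):
            dropped = [s for s, r in zip(self.species, row) if r <= 0]
            logger.warning("dropping %d species with zero total abundance: %s",
                           len(dropped), dropped)
            keep = row > 0
            object.__setattr__(
                self, "species",
                tuple(np.array(self.species, dtype=object)[keep]),
            )
            z = z[keep]
        object.__setattr__(self, "z", z)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_assemblages(self) -> int:
        return len(self.assemblages)

    def column(self, key: int | str) -> AbundanceVector:
        """Abundance vector of one assemblage (species with zero abundance
        in that assemblage retained, so labels match across columns)."""
        if isinstance(key, str):
            try:
                k = self.assemblages.index(key)
            except ValueError:
                raise AlignmentError(f"no assemblage named {key!r}", (key,))
        else:
            k = int(key)
        return AbundanceVector(self.species, self.z[:, k])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(
            tuple(str(x) for x in df.index),
            tuple(str(x) for x in df.columns),
            df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.species, columns=self.assemblages)


def align_distance(
    dm: DistanceMatrix, labels: Sequence[str]
) -> np.ndarray:
    """Distance submatrix re-indexed to ``labels``; raises AlignmentError
    listing the species that are missing from the matrix."""
    return dm.submatrix(labels).values


def restrict_to_distance(
    Z: CommunityMatrix, dm: DistanceMatrix
) -> tuple[CommunityMatrix, np.ndarray]:
    """Align a community matrix with a distance matrix.

    Species in ``Z`` missing from ``dm`` are a hard error; species in ``dm``
    absent from ``Z`` are dropped with a logged warning.  Returns the
    (unchanged) community matrix and the distance submatrix in ``Z``'s
    species order.
    """
    missing = tuple(s for s in Z.species if s not in dm.labels)
    if missing:
        raise AlignmentError(
            f"species in community data but not in distance matrix: {list(missing)}",
            missing,
        )
    extra = [s for s in dm.labels if s not in Z.species]
    if extra:
        logger.warning(
            "dropping %d species present in the distance matrix but not in "
            "the community data: %s", len(extra), extra
        )
    return Z, align_distance(dm, Z.species)
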