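"""Readers and writers for the package's CSV/TSV interchange formats.

Distance matrices: first row and first column are species labels, square
numeric body; a lower-triangle file (upper cells empty) can be completed by
symmetry.  Abundance tables: rows are species (first column), columns are
assemblages (header row).  Trait tables come with a sidecar YAML/JSON file
mapping each trait column to its type.  Results are written as long-format
CSV (measure, q, scheme, assemblage_or_pair, value) or as JSON with full
precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import CommunityMatrix, DistanceMatrix
from .errors import ValidationError
from .traits import TraitTable

__all__ = [
    "read_distance",
    "read_abundance",
    "read_traits",
    "write_distance",
    "write_abundance",
    "results_frame",
    "write_results",
    "convert_xlsx_matrices",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pandas raises many types on ragged/bad files
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def read_distance(
    path: str | Path,
    lower_triangle: bool = False,
    symmetrize: str | None = None,
) -> DistanceMatrix:
    """Read a labelled square distance matrix from CSV/TSV.

    ``lower_triangle=True`` accepts a file whose upper triangle is empty and
    fills it by symmetry.  ``symmetrize="mean"`` averages (i, j) and (j, i)
    instead of erroring on asymmetry beyond tolerance.
    """
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{path}: distance matrix must be square, got {df.shape}"
        )
    if list(df.index) != list(df.columns):
        raise ValidationError(
            f"{path}: row labels must equal column labels in the same order"
        )
    v = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if lower_triangle:
        upper_nan = np.isnan(v) & (np.arange(len(v))[:, None] < np.arange(len(v))[None, :])
        v = np.where(upper_nan, v.T, v)
        v = np.where(np.isnan(v) & np.eye(len(v), dtype=bool), 0.0, v)
    bad = np.argwhere(np.isnan(v))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-numeric or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if symmetrize == "mean":
        v = (v + v.T) / 2.0
    elif symmetrize is not None:
        raise ValidationError(f"unknown symmetrize mode {symmetrize!r}")
    return DistanceMatrix(tuple(df.index), v)


def read_abundance(path: str | Path) -> CommunityMatrix:
    """Read a species × assemblage abundance table from CSV/TSV."""
    df = _read_table(path)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(num.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return CommunityMatrix.from_dataframe(num)


def read_traits(path: str | Path, types_path: str | Path) -> TraitTable:
    """Read a species × trait table plus its YAML/JSON trait-type sidecar."""
    df = _read_table(path)
    tp = Path(types_path)
    if not tp.exists():
        raise ValidationError(f"trait-type file not found: {tp}")
    text = tp.read_text()
    types: Mapping[str, str]
    if tp.suffix.lower() == ".json":
        types = json.loads(text)
    else:
        types = yaml.safe_load(text)
    if not isinstance(types, dict):
        raise ValidationError(f"{tp}: expected a mapping of trait -> type")
    return TraitTable(df, {str(k): str(v) for k, v in types.items()})


def write_distance(dm: DistanceMatrix, path: str | Path) -> None:
    path = Path(path)
    dm.to_dataframe().to_csv(path, sep=_sep_for(path))


def write_abundance(Z: CommunityMatrix, path: str | Path) -> None:
    path = Path(path)
    Z.to_dataframe().to_csv(path, sep=_sep_for(path))


def results_frame(records: Sequence[Mapping]) -> pd.DataFrame:
    """Long-format result table with the canonical column order."""
    df = pd.DataFrame(list(records))
    cols = ["measure", "q", "scheme", "assemblage_or_pair", "value"]
    for c in cols:
        if c not in df.columns:
            df[c] = None
    return df[cols]


def _sig(x, digits: int = 6):
    if isinstance(x, float) and math.isfinite(x) and x != 0:
        return float(f"{x:.{digits}g}")
    return x


def write_results(
    records: Sequence[Mapping], path: str | Path, fmt: str | None = None
) -> None:
    """Write result records as long CSV (6 significant digits) or JSON
    (full precision); format inferred from the extension when not given."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps(list(records), indent=2, default=float))
    elif fmt == "csv":
        df = results_frame(records)
        df["value"] = df["value"].map(_sig)
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown output format {fmt!r}")


def convert_xlsx_matrices(path: str | Path, out_dir: str | Path) -> list[Path]:
    """Convert every sheet of a supplementary spreadsheet of distance
    matrices to labelled CSV files (one per sheet).  Requires openpyxl."""
    path = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    written = []
    for name, df in sheets.items():
        target = out_dir / f"{name}.csv"
        df.to_csv(target)
        written.append(target)
    return written
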