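"""Readers, writers and preprocessing for cell tables.

Delimited text (comma or tab, auto-detected; cells are rows, markers are
columns) and list-mode FCS 3.0/3.1 files are read into a
:class:`~tides.trajectory.CellTable`.  Preprocessing covers the standard
cytometry arcsinh transform (cofactor 5) and right-tail trimming of the
conditioning marker.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import CellTable, normalize_pseudotime


@dataclass
class PreprocessConfig:
    arcsinh_cofactor: float = 5.0
    tail_trim_count: int = 50
    gate_spec: object | None = None      # optional GateSpec exclusion/classification
    marker_subset: list | None = None

    def __post_init__(self):
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")
        if self.tail_trim_count < 0:
            raise ValueError("tail_trim_count must be >= 0")

    def apply(self, cells: "CellTable") -> "CellTable":
        """Arcsinh-transform and optionally restrict to a marker subset.

        Tail trimming is deferred to the per-edge analyses (it is specific
        to the conditioning marker), and the gate spec, when present, is
        applied by the caller as a classification or exclusion step.
        """
        out = arcsinh_transform(cells, self.arcsinh_cofactor)
        if self.marker_subset is not None:
            out = CellTable(expression=out.expression[list(self.marker_subset)],
                            pseudotime=out.pseudotime, condition=out.condition)
        return out


def _read_delimited(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: missing header line")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    names = [h.strip() for h in header.strip().split(sep)]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:  # pandas would silently mangle these to A, A.1, ...
        raise ValueError(f"{path}: duplicated marker name(s): {dupes}")
    df = pd.read_csv(path, sep=sep, comment="#")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric column(s): {non_numeric}")
    return df


def _read_fcs(path: Path) -> pd.DataFrame:
    """Minimal list-mode FCS 3.0/3.1 reader (float or double data)."""
    raw = Path(path).read_bytes()
    version = raw[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    text_start, text_end = int(raw[10:18]), int(raw[18:26])
    text = raw[text_start:text_end + 1].decode("latin-1")
    delim = text[0]
    parts = text[1:].split(delim)
    kw = {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    dtype = kw["$DATATYPE"].upper()
    if dtype not in ("F", "D"):
        raise ValueError(f"{path}: only float ($DATATYPE F/D) data supported, got {dtype!r}")
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError(f"{path}: only list mode supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    width = 4 if dtype == "F" else 8
    count = n_par * n_tot
    buf = raw[data_start:data_start + count * width]
    if len(buf) < count * width:
        raise ValueError(f"{path}: data segment truncated "
                         f"(expected {count * width} bytes, found {len(buf)}; ends at {data_end})")
    fmt = ("<" if little else ">") + ("f" if dtype == "F" else "d")
    values = np.frombuffer(buf, dtype=np.dtype(fmt)).astype(float)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(values.reshape(n_tot, n_par), columns=names)


def read_cells(path, fmt: str | None = None, pseudotime_column: str | None = None,
               pseudotime_file=None, condition: str | None = None) -> CellTable:
    """Load a cell table from delimited text or FCS.

    Pseudotime may come from a named column of the table or from a
    separate single-column text file aligned by cell order; either way
    it is normalized onto [0, 1].
    """
    path = Path(path)
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if fmt == "fcs":
        df = _read_fcs(path)
    elif fmt == "delimited":
        df = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'fcs' or 'delimited'")

    pseudotime = None
    if pseudotime_column is not None:
        if pseudotime_column not in df.columns:
            raise ValueError(f"pseudotime column {pseudotime_column!r} not found in {path}")
        pseudotime = normalize_pseudotime(df.pop(pseudotime_column).to_numpy(float))
    elif pseudotime_file is not None:
        raw = np.loadtxt(pseudotime_file, ndmin=1)
        if raw.shape[0] != len(df):
            raise ValueError(f"pseudotime file has {raw.shape[0]} values for {len(df)} cells")
        pseudotime = normalize_pseudotime(raw)
    return CellTable(expression=df, pseudotime=pseudotime, condition=condition)


def write_cells(cells: CellTable, path, sep: str = ",") -> None:
    """Write a cell table (plus pseudotime column if present) as delimited text."""
    df = cells.expression.copy()
    if cells.pseudotime is not None:
        df["pseudotime"] = cells.pseudotime
    df.to_csv(path, sep=sep, index=False)


def arcsinh_transform(cells: CellTable, cofactor: float = 5.0) -> CellTable:
    """Variance-stabilizing transform x -> asinh(x / cofactor) per entry."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return CellTable(expression=np.arcsinh(cells.expression / cofactor),
                     pseudotime=cells.pseudotime, condition=cells.condition)


def trim_right_tail(cells: CellTable, marker: str, k: int = 50) -> CellTable:
    """Drop the k cells with the largest values of a marker.

    Keeps the conditioning marker's dynamic range well populated by
    removing its sparse right tail.  Ties are broken by stable input
    order (earlier cells kept).
    """
    if k == 0:
        return cells
    if k >= cells.n_cells:
        raise ValueError(f"cannot trim {k} cells from a table of {cells.n_cells}")
    values = cells.marker(marker)
    order = np.argsort(values, kind="stable")  # ascending; ties keep input order
    drop = order[-k:]
    keep = np.ones(cells.n_cells, dtype=bool)
    keep[drop] = False
    return cells.subset(keep)
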