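"""CSV readers and writers.

One canonical dialect: comma-separated UTF-8, factor codes as the first
header row and first column, identical order on both axes.  Integer
matrices round-trip losslessly; real matrices are written at a configured
decimal precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MatrixFormatError
from .factors import FactorInfo, FactorSystem
from .matrices import DirectInfluenceMatrix

__all__ = [
    "read_matrix_csv",
    "read_real_matrix_csv",
    "write_matrix_csv",
    "read_labels_csv",
    "write_labels_csv",
]


def _read_grid(path: str | Path) -> tuple[FactorSystem, pd.DataFrame]:
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: malformed CSV ({exc})") from None
    cols = [str(c) for c in frame.columns]
    rows = [str(r) for r in frame.index]
    for axis, codes in (("column", cols), ("row", rows)):
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise MatrixFormatError(f"{path}: duplicated {axis} code(s) {sorted(dupes)}")
    if cols != rows:
        raise MatrixFormatError(
            f"{path}: row codes {rows} do not match column codes {cols}"
        )
    for r in rows:
        for c in cols:
            cell = frame.at[r, c]
            try:
                float(cell)
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"{path}: non-numeric cell at row {r!r}, column {c!r}: {cell!r}"
                ) from None
    return FactorSystem(tuple(cols)), frame.astype(float)


def read_matrix_csv(path: str | Path) -> DirectInfluenceMatrix:
    """Read an aggregated direct-influence matrix (integer entries)."""
    system, frame = _read_grid(path)
    values = frame.to_numpy()
    if not np.array_equal(values, np.round(values)):
        raise MatrixFormatError(f"{path}: direct influence entries must be integers")
    return DirectInfluenceMatrix(system, values.astype(np.int64))


def read_real_matrix_csv(path: str | Path) -> tuple[FactorSystem, np.ndarray]:
    """Read a real-valued factor matrix; returns (system, array)."""
    system, frame = _read_grid(path)
    return system, frame.to_numpy()


def write_matrix_csv(matrix, path: str | Path, precision: int | None = None) -> None:
    """Write any pipeline matrix (an object with .to_frame(), a DataFrame,
    or a (system, array) pair) in the canonical dialect.

    ``precision`` rounds real values to that many decimals; integers are
    written exactly.
    """
    if hasattr(matrix, "to_frame"):
        frame = matrix.to_frame()
    elif isinstance(matrix, pd.DataFrame):
        frame = matrix
    else:
        system, values = matrix
        frame = pd.DataFrame(values, index=system.codes, columns=system.codes)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if precision is not None and not np.issubdtype(frame.to_numpy().dtype, np.integer):
        frame.to_csv(path, float_format=f"%.{precision}f")
    else:
        frame.to_csv(path)


def read_labels_csv(path: str | Path) -> dict[str, FactorInfo]:
    """Read a label table: code, name, dimension, description."""
    path = Path(path)
    labels: dict[str, FactorInfo] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MatrixFormatError(f"{path}: label table needs at least columns {sorted(required)}")
        for row in reader:
            code = row["code"]
            if code in labels:
                raise MatrixFormatError(f"{path}: duplicated factor code {code!r}")
            labels[code] = FactorInfo(
                name=row["name"],
                dimension=row.get("dimension", "") or "",
                description=row.get("description", "") or "",
            )
    return labels


def write_labels_csv(system: FactorSystem, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name", "dimension", "description"])
        for code in system.codes:
            info = system.info(code)
            writer.writerow([code, info.name, info.dimension, info.description])
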