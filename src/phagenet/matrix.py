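"""Binary phage-bacteria infection matrices.

The central object is :class:`InfectionMatrix`: a labelled binary matrix
``A`` in which rows are bacterial phage types (PTs), columns are typing
phages (TPs), and ``A[i, j] = 1`` records that typing phage *j* lyses phage
type *i*.  All downstream structure measures (nestedness, bipartite
modularity, null models, clustering) consume this object and share its
symbol conventions:

``r``/``c``
    number of rows (PTs) / columns (TPs),
``k_i``/``d_j``
    row and column degrees (number of 1s),
``F``
    total number of interactions (edges),
``M = r * c``
    maximum possible interactions.

Orientation is fixed: rows are always bacteria, columns are always phages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfectionMatrix",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "degree_profiles",
]


class MatrixValidationError(ValueError):
    """A loaded or constructed matrix violates the binary-matrix contract."""


class MatrixFormatError(ValueError):
    """A delimited-text file does not parse as a labelled binary matrix."""


@dataclass(frozen=True)
class InfectionMatrix:
    """Labelled binary bipartite interaction matrix.

    Parameters
    ----------
    entries
        2-D array coercible to integers, every value exactly 0 or 1.
    row_labels, col_labels
        Unique, nonempty identifiers for PTs (rows) and TPs (columns).
    """

    entries: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.entries)
        if a.ndim != 2:
            raise MatrixValidationError(f"expected a 2-D matrix, got ndim={a.ndim}")
        bad = ~np.isin(a, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary value {a[i, j]!r} at row {i} "
                f"({self.row_labels[i] if i < len(self.row_labels) else '?'}), "
                f"column {j} "
                f"({self.col_labels[j] if j < len(self.col_labels) else '?'})"
            )
        a = a.astype(np.int8)
        a.setflags(write=False)
        object.__setattr__(self, "entries", a)
        object.__setattr__(self, "row_labels", tuple(str(x) for x in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(x) for x in self.col_labels))
        for name, labels, n in (
            ("row", self.row_labels, a.shape[0]),
            ("column", self.col_labels, a.shape[1]),
        ):
            if len(labels) != n:
                raise MatrixValidationError(
                    f"{len(labels)} {name} labels for {n} {name}s"
                )
            if any(not lab for lab in labels):
                raise MatrixValidationError(f"empty {name} label")
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(x for x in labels if x in seen or seen.add(x))
                raise MatrixValidationError(f"duplicate {name} label {dup!r}")

    # -- matrix-level symbols -------------------------------------------------

    @property
    def r(self) -> int:
        """Number of rows (phage types)."""
        return self.entries.shape[0]

    @property
    def c(self) -> int:
        """Number of columns (typing phages)."""
        return self.entries.shape[1]

    @property
    def row_degrees(self) -> np.ndarray:
        """k_i: number of phages infecting each bacterium."""
        return self.entries.sum(axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        """d_j: number of bacteria infected by each phage."""
        return self.entries.sum(axis=0)

    @property
    def F(self) -> int:
        """Total number of interactions (edges)."""
        return int(self.entries.sum())

    @property
    def M(self) -> int:
        """Maximum possible interactions, r * c."""
        return self.r * self.c

    @property
    def fill(self) -> float:
        """Connectance F/M (0 for an empty 0x0 matrix)."""
        return self.F / self.M if self.M else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.entries, dtype=int),
            index=list(self.row_labels),
            columns=list(self.col_labels),
        )

    def permuted(self, row_order: Sequence[int] | None = None,
                 col_order: Sequence[int] | None = None) -> "InfectionMatrix":
        """Return a copy with rows/columns reordered (labels follow)."""
        ri = np.arange(self.r) if row_order is None else np.asarray(row_order)
        ci = np.arange(self.c) if col_order is None else np.asarray(col_order)
        return InfectionMatrix(
            self.entries[np.ix_(ri, ci)],
            tuple(self.row_labels[i] for i in ri),
            tuple(self.col_labels[j] for j in ci),
        )


_DELIMS = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t", "csv": ",", "tsv": "\t"}


def read_matrix(path: str | Path, dialect: str = "comma") -> InfectionMatrix:
    """Read a labelled binary matrix from delimited text.

    The first row holds typing-phage (column) labels; the first field of
    each subsequent row is the phage-type (row) label; remaining fields
    must be 0 or 1.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"comma"`` (default) or ``"tab"``.
    """
    sep = _DELIMS.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise MatrixFormatError(f"{path}: need a header row and at least one data row")
    header = lines[0].split(sep)
    col_labels = [f.strip() for f in header[1:]]
    ncol = len(col_labels)
    row_labels: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in ln.split(sep)]
        if len(fields) - 1 != ncol:
            raise MatrixFormatError(
                f"{path}:{lineno}: ragged row — {len(fields) - 1} values, "
                f"expected {ncol}"
            )
        row_labels.append(fields[0])
        vals = []
        for j, f in enumerate(fields[1:]):
            if f not in ("0", "1"):
                raise MatrixValidationError(
                    f"{path}:{lineno}: non-binary value {f!r} at row "
                    f"{fields[0]!r}, column {col_labels[j]!r}"
                )
            vals.append(int(f))
        rows.append(vals)
    return InfectionMatrix(np.array(rows, dtype=np.int8),
                           tuple(row_labels), tuple(col_labels))


def write_matrix(m: InfectionMatrix, path: str | Path,
                 dialect: str = "comma") -> None:
    """Write in the canonical labelled delimited-text layout (round-trips
    with :func:`read_matrix`)."""
    sep = _DELIMS.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    lines = [sep.join(["PT"] + list(m.col_labels))]
    for lab, row in zip(m.row_labels, np.asarray(m.entries, dtype=int)):
        lines.append(sep.join([lab] + [str(v) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def degree_profiles(m: InfectionMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Return ``(row_degrees, col_degrees, fill)`` for *m*."""
    return m.row_degrees, m.col_degrees, m.fill
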