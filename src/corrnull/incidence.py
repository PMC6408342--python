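"""Binary incidence matrices and directed food webs.

The central object of the framework is a labelled binary incidence matrix
``A`` (n rows × m columns): species × sites, hosts × parasites, or — as a
square special case — a directed food-web adjacency where ``A[i, j] = 1``
means *consumer i eats resource j*.  Everything downstream (probability
estimation, swap randomization, structure metrics) operates on these two
types.

Direction convention for food webs
----------------------------------
Rows are consumers, columns are resources: ``values[i, j] = 1`` encodes the
trophic link "i eats j".  The two probability-estimation perspectives
(predator's diet vs prey's consumers) depend on this orientation, so it is
fixed package-wide and never inferred from data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "FoodWeb",
    "LinkClassSummary",
    "read_incidence",
    "write_incidence",
    "classify_links",
]


class FormatError(ValueError):
    """Raised when an input file does not parse as a valid binary matrix."""


def _check_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-d matrix, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, [0, 1])):
        bad = [u for u in uniq.tolist() if u not in (0, 1)]
        raise FormatError(
            f"matrix entries must be exactly 0 or 1; found {bad}. "
            "Values > 1 are rejected, not coerced: the method is defined on "
            "presence/absence only."
        )
    return arr.astype(np.int8)


def _check_labels(labels, axis_name: str, expected: int) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != expected:
        raise FormatError(
            f"{axis_name} labels: expected {expected}, got {len(labels)}"
        )
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate {axis_name} labels")
    return labels


@dataclass
class IncidenceMatrix:
    """Labelled binary n×m matrix with n, m ≥ 2 and unique labels."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = _check_binary(self.values)
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise FormatError(
                f"need at least 2 rows and 2 columns for randomization, got {n}×{m}"
            )
        self.row_labels = _check_labels(self.row_labels, "row", n)
        self.col_labels = _check_labels(self.col_labels, "column", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_links(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "IncidenceMatrix":
        return IncidenceMatrix(
            self.values.copy(), list(self.row_labels), list(self.col_labels)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.col_labels
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.values, other.values)
        )


@dataclass
class FoodWeb:
    """Square directed adjacency; ``values[i, j] = 1`` ⇔ consumer i eats j."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = _check_binary(self.values)
        n, m = self.values.shape
        if n != m:
            raise FormatError(f"food web adjacency must be square, got {n}×{m}")
        if n < 2:
            raise FormatError("food web needs at least 2 species")
        self.labels = _check_labels(self.labels, "species", n)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "FoodWeb":
        return FoodWeb(self.values.copy(), list(self.labels))

    def as_incidence(self) -> IncidenceMatrix:
        """View the adjacency as a consumers × resources incidence matrix."""
        return IncidenceMatrix(self.values.copy(), list(self.labels), list(self.labels))

    @classmethod
    def from_incidence(cls, A: IncidenceMatrix) -> "FoodWeb":
        if A.row_labels != A.col_labels:
            raise FormatError(
                "square matrix with identical row/column labels required for a food web"
            )
        return cls(A.values.copy(), list(A.row_labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values
        )


@dataclass
class LinkClassSummary:
    """Exact disjoint decomposition of a food web's links.

    ``cannibal`` links are self-loops, ``double`` links are reciprocal pairs
    (counted once per unordered pair), ``single`` links are all remaining
    directed links.  ``n_single + 2·n_double + n_cannibal`` equals the total
    number of 1-entries.
    """

    n_single: int
    n_double: int
    n_cannibal: int
    in_degree: dict[str, int] = field(default_factory=dict)
    out_degree: dict[str, int] = field(default_factory=dict)

    @property
    def total_links(self) -> int:
        return self.n_single + 2 * self.n_double + self.n_cannibal


def classify_links(W: FoodWeb) -> LinkClassSummary:
    """Decompose a food web's links into single / double / cannibal classes."""
    A = W.values
    diag = np.diag(A).astype(bool)
    n_cannibal = int(diag.sum())
    off = A.copy()
    np.fill_diagonal(off, 0)
    mutual = off & off.T
    n_double = int(mutual.sum()) // 2
    n_single = int(off.sum()) - int(mutual.sum())
    out_deg = {lab: int(A[i].sum()) for i, lab in enumerate(W.labels)}
    in_deg = {lab: int(A[:, i].sum()) for i, lab in enumerate(W.labels)}
    return LinkClassSummary(n_single, n_double, n_cannibal, in_deg, out_deg)


# ---------------------------------------------------------------------------
# I/O


def _sniff_sep(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_incidence(path, format: str = "matrix_csv") -> IncidenceMatrix:
    """Read a labelled binary matrix from ``matrix_csv`` or ``edge_list``.

    ``matrix_csv``: row labels in the first column, column labels in the
    header; comma- or tab-delimited (auto-detected).  ``edge_list``:
    header-less two-column file, one ``row_label, col_label`` link per line;
    labels appear in the matrix in first-appearance order.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_sep(first)
    if format == "matrix_csv":
        header = [h.strip() for h in first.rstrip("\n").split(sep)[1:]]
        if len(set(header)) != len(header):
            raise FormatError(f"{path}: duplicate column labels in header")
        df = pd.read_csv(path, index_col=0, sep=sep)
        try:
            values = _check_binary(df.to_numpy())
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        return IncidenceMatrix(values, list(df.index), list(df.columns))
    if format == "edge_list":
        df = pd.read_csv(path, header=None, sep=sep, dtype=str)
        if df.shape[1] != 2:
            raise FormatError(
                f"{path}: edge list must have exactly two columns, got {df.shape[1]}"
            )
        pairs = list(df.itertuples(index=False, name=None))
        if len(set(pairs)) != len(pairs):
            dupes = {p for p in pairs if pairs.count(p) > 1}
            raise FormatError(f"{path}: duplicate links {sorted(dupes)}")
        rows = list(dict.fromkeys(r for r, _ in pairs))
        cols = list(dict.fromkeys(c for _, c in pairs))
        values = np.zeros((len(rows), len(cols)), dtype=np.int8)
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for r, c in pairs:
            values[ri[r], ci[c]] = 1
        return IncidenceMatrix(values, rows, cols)
    raise ValueError(f"unknown format {format!r}")


def write_incidence(A: IncidenceMatrix, path, format: str = "matrix_csv") -> None:
    """Write a matrix so that :func:`read_incidence` round-trips it exactly.

    The edge-list format cannot represent rows or columns with no links;
    writing such a matrix as an edge list emits a warning because the
    round-trip drops the empty rows/columns.
    """
    path = str(path)
    if format == "matrix_csv":
        A.to_frame().to_csv(path)
    elif format == "edge_list":
        if (A.values.sum(axis=1) == 0).any() or (A.values.sum(axis=0) == 0).any():
            warnings.warn(
                "matrix has empty rows or columns; edge-list format drops them "
                "on round-trip",
                stacklevel=2,
            )
        with open(path, "w") as fh:
            for i, r in enumerate(A.row_labels):
                for j, c in enumerate(A.col_labels):
                    if A.values[i, j]:
                        fh.write(f"{r},{c}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
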