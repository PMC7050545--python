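"""Reading, validation and filtering of weighted bipartite interaction matrices.

The central data contract is :class:`InteractionMatrix`: a labeled plant × ant
matrix of non-negative integer visit counts.  Plants are canonically rows (the
lower trophic level); files stored the other way round are transposed at read
time.  Attribute tables (one per guild) carry the categorical and continuous
covariates used downstream by the ordination fitting and the univariate tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Guild = Literal["plant", "ant"]

#: Allowed categorical levels per guild attribute column.
CATEGORICAL_LEVELS = {
    "efn_distribution": {"C", "D"},
    "habitat": {"O", "S", "B"},
    "invasive": {"INV", "NO"},
    "dominance": {"A", "B", "C", "D", "E", "F"},
}

_CONTINUOUS_POSITIVE = {"cover", "head_length"}


class MatrixValidationError(ValueError):
    """Raised when a matrix or attribute table violates its contract."""


class MatrixParseError(ValueError):
    """Raised when a file cell cannot be parsed; carries row/col coordinates."""


@dataclass(frozen=True)
class InteractionMatrix:
    """A validated weighted bipartite plant × ant interaction matrix.

    Parameters
    ----------
    plant_labels :
        Unique plant species names, one per row.
    ant_labels :
        Unique ant species names, one per column.
    weights :
        Non-negative integer visit counts, shape ``(n_plants, n_ants)``.
        After validation no row or column is entirely zero and the total
        count is positive.
    """

    plant_labels: tuple[str, ...]
    ant_labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2:
            raise MatrixValidationError("weights must be a 2-D array")
        if w.shape != (len(self.plant_labels), len(self.ant_labels)):
            raise MatrixValidationError(
                f"weights shape {w.shape} does not match labels "
                f"({len(self.plant_labels)} plants, {len(self.ant_labels)} ants)"
            )
        if w.size == 0:
            raise MatrixValidationError("empty matrix")
        if np.issubdtype(w.dtype, np.floating):
            if not np.all(np.isfinite(w)):
                raise MatrixValidationError("non-finite weight")
            if np.any(w != np.floor(w)):
                bad = np.argwhere(w != np.floor(w))[0]
                raise MatrixValidationError(
                    f"non-integer weight at row {bad[0]}, col {bad[1]}: counts must be integers"
                )
            w = w.astype(np.int64)
        else:
            w = w.astype(np.int64)
        if np.any(w < 0):
            bad = np.argwhere(w < 0)[0]
            raise MatrixValidationError(f"negative weight at row {bad[0]}, col {bad[1]}")
        for guild, labels in (("plant", self.plant_labels), ("ant", self.ant_labels)):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise MatrixValidationError(f"duplicate {guild} label: {lab!r}")
                seen.add(lab)
        if w.sum() == 0:
            raise MatrixValidationError("matrix has no interactions (total weight 0)")
        if np.any(w.sum(axis=1) == 0):
            i = int(np.argmin(w.sum(axis=1)))
            raise MatrixValidationError(
                f"all-zero row for plant {self.plant_labels[i]!r}"
            )
        if np.any(w.sum(axis=0) == 0):
            j = int(np.argmin(w.sum(axis=0)))
            raise MatrixValidationError(f"all-zero column for ant {self.ant_labels[j]!r}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "plant_labels", tuple(self.plant_labels))
        object.__setattr__(self, "ant_labels", tuple(self.ant_labels))
        self.weights.setflags(write=False)

    # -- derived quantities -------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_ants(self) -> int:
        return len(self.ant_labels)

    @property
    def n_links(self) -> int:
        """L: number of realized (nonzero) plant–ant associations."""
        return int(np.count_nonzero(self.weights))

    @property
    def total_frequency(self) -> int:
        """F: total interaction frequency summed over all cells."""
        return int(self.weights.sum())

    def binary(self) -> np.ndarray:
        """Presence/absence (0/1 int) view of the matrix."""
        return (self.weights > 0).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.plant_labels), columns=list(self.ant_labels)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionMatrix":
        return cls(
            plant_labels=tuple(str(i).strip() for i in df.index),
            ant_labels=tuple(str(c).strip() for c in df.columns),
            weights=df.to_numpy(),
        )


@dataclass(frozen=True)
class SpeciesAttributes:
    """Per-species covariates for one guild, indexed by species label."""

    guild: Guild
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise MatrixValidationError(f"duplicate species label: {dup!r}")
        for col in self.table.columns:
            if col in CATEGORICAL_LEVELS:
                allowed = CATEGORICAL_LEVELS[col]
                values = self.table[col].dropna()
                bad = set(values) - allowed
                if bad:
                    raise MatrixValidationError(
                        f"unknown level {sorted(bad)[0]!r} in column {col!r} "
                        f"(allowed: {sorted(allowed)})"
                    )
            elif col in _CONTINUOUS_POSITIVE:
                vals = pd.to_numeric(self.table[col], errors="coerce")
                if vals.isna().any() or not np.all(np.isfinite(vals)):
                    raise MatrixValidationError(f"non-numeric value in column {col!r}")
                if (vals <= 0).any():
                    raise MatrixValidationError(f"non-positive value in column {col!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def aligned_to(self, labels: Sequence[str]) -> pd.DataFrame:
        """Rows of the table reordered to ``labels``; missing species is an error."""
        missing = [lab for lab in labels if lab not in self.table.index]
        if missing:
            raise MatrixValidationError(
                f"species missing from {self.guild} attribute table: {missing[0]!r}"
            )
        return self.table.loc[list(labels)]


# -- file I/O ----------------------------------------------------------------


def _read_labeled_table(path: str | Path) -> pd.DataFrame:
    """Read a labeled CSV/TSV with auto-detected delimiter."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    header = [h.strip().strip('"') for h in first.split(sep)[1:]]
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise MatrixValidationError(f"duplicate column label: {sorted(dups)[0]!r}")
    return pd.read_csv(io.StringIO(text), sep=sep, index_col=0)


def read_matrix(
    path: str | Path, orientation: Literal["plants_rows", "ants_rows"] = "plants_rows"
) -> InteractionMatrix:
    """Read a labeled interaction matrix; plants become rows regardless of file layout.

    The first column holds row labels and the header row holds column labels.
    Cells must parse as non-negative integers (decimals are rejected, not
    rounded, because the data are visit counts).
    """
    df = _read_labeled_table(path)
    if df.size == 0:
        raise MatrixValidationError(f"empty matrix in {path}")
    if orientation == "ants_rows":
        df = df.T
    arr = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for (i, j), val in np.ndenumerate(raw):
        try:
            x = float(val)
        except (TypeError, ValueError):
            raise MatrixParseError(
                f"non-numeric cell {val!r} at row {df.index[i]!r}, col {df.columns[j]!r}"
            ) from None
        if not np.isfinite(x) or x < 0:
            raise MatrixParseError(
                f"negative or non-finite cell {val!r} at row {df.index[i]!r}, "
                f"col {df.columns[j]!r}"
            )
        if x != int(x):
            raise MatrixParseError(
                f"non-integer cell {val!r} at row {df.index[i]!r}, col {df.columns[j]!r}"
            )
        arr[i, j] = int(x)
    return InteractionMatrix(
        plant_labels=tuple(str(i).strip() for i in df.index),
        ant_labels=tuple(str(c).strip() for c in df.columns),
        weights=arr,
    )


def write_matrix(m: InteractionMatrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    m.to_frame().to_csv(path, sep=sep, index_label="species")


def read_attributes(path: str | Path, guild: Guild) -> SpeciesAttributes:
    """Read a per-species attribute table; the first column is the species label."""
    df = _read_labeled_table(path)
    if df.shape[1] < 1:
        raise MatrixValidationError("attribute table needs at least one attribute column")
    df.index = [str(i).strip() for i in df.index]
    for col in df.columns:
        if col in CATEGORICAL_LEVELS:
            df[col] = df[col].astype(str).str.strip()
    return SpeciesAttributes(guild=guild, table=df)


# -- transformations ---------------------------------------------------------


def filter_rare_interactions(m: InteractionMatrix, min_count: int = 3) -> InteractionMatrix:
    """Zero out cells below ``min_count`` visits and drop species left without links.

    Rare pairwise records (seen on fewer than ``min_count`` occasions across
    the censuses) are removed so that very rare species are not mistaken for
    specialists, which would inflate specialization and nestedness estimates.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    w = m.weights.copy()
    w[w < min_count] = 0
    keep_rows = w.sum(axis=1) > 0
    keep_cols = w.sum(axis=0) > 0
    if not keep_rows.any() or not keep_cols.any():
        raise MatrixValidationError("no interactions survive filter")
    return InteractionMatrix(
        plant_labels=tuple(np.asarray(m.plant_labels)[keep_rows]),
        ant_labels=tuple(np.asarray(m.ant_labels)[keep_cols]),
        weights=w[np.ix_(keep_rows, keep_cols)],
    )


def to_edge_list(m: InteractionMatrix) -> list[tuple[str, str, int]]:
    """All nonzero cells as (plant, ant, weight) triples; exactly L entries."""
    rows, cols = np.nonzero(m.weights)
    return [
        (m.plant_labels[i], m.ant_labels[j], int(m.weights[i, j]))
        for i, j in zip(rows, cols)
    ]


def from_edge_list(edges: Iterable[tuple[str, str, int]]) -> InteractionMatrix:
    """Build a matrix from (plant, ant, weight) triples, summing duplicates."""
    edges = list(edges)
    plants: list[str] = []
    ants: list[str] = []
    for p, a, _ in edges:
        if p not in plants:
            plants.append(p)
        if a not in ants:
            ants.append(a)
    w = np.zeros((len(plants), len(ants)), dtype=np.int64)
    for p, a, wt in edges:
        w[plants.index(p), ants.index(a)] += int(wt)
    return InteractionMatrix(tuple(plants), tuple(ants), w)
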