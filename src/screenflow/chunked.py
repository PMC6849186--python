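"""Out-of-core table abstraction and streaming map-reduce numerics.

A :class:`ChunkedTable` is an ordered sequence of dense row blocks sharing one
column schema. Every statistic in the package is computed as an associative
reduction over these blocks, so results are invariant to how the rows are
partitioned and no operation ever needs more than one block of rows plus
O(n_columns^2) accumulator state in memory at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_ROWS = 100_000


@dataclass
class ChunkedTable:
    """A numeric table stored as an ordered sequence of row partitions.

    Parameters
    ----------
    column_names
        Ordered column labels, shared by every partition.
    partitions
        Row blocks, each a dense ``(rows_in_block, n_columns)`` float array.
    """

    column_names: list[str]
    partitions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.column_names = list(self.column_names)
        p = len(self.column_names)
        parts = []
        for block in self.partitions:
            a = np.asarray(block, dtype=float)
            if a.ndim != 2 or a.shape[1] != p:
                raise DataError(
                    f"partition of shape {a.shape} does not match "
                    f"{p} columns"
                )
            parts.append(a)
        self.partitions = parts

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return sum(b.shape[0] for b in self.partitions)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def iter_partitions(self) -> Iterator[np.ndarray]:
        """Yield row blocks one at a time; the streaming access path."""
        yield from self.partitions

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_array(
        cls,
        x: np.ndarray,
        column_names: Sequence[str],
        chunk_rows: int = DEFAULT_CHUNK_ROWS,
    ) -> "ChunkedTable":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if chunk_rows < 1:
            raise ValueError("chunk_rows must be >= 1")
        blocks = [
            x[i : i + chunk_rows] for i in range(0, x.shape[0], chunk_rows)
        ]
        return cls(list(column_names), blocks)

    def materialize(self) -> np.ndarray:
        """Concatenate all partitions into one dense matrix."""
        if not self.partitions:
            return np.empty((0, self.n_columns))
        return np.concatenate(self.partitions, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.materialize(), columns=self.column_names)

    # -- column / row selection ----------------------------------------------

    def _col_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise DataError(
                f"column {name!r} not in table (have {self.column_names})"
            ) from None

    def select(self, columns: Sequence[str]) -> "ChunkedTable":
        idx = [self._col_index(c) for c in columns]
        return ChunkedTable(
            list(columns), [b[:, idx] for b in self.partitions]
        )

    def drop(self, columns: Sequence[str]) -> "ChunkedTable":
        keep = [c for c in self.column_names if c not in set(columns)]
        return self.select(keep)

    def column(self, name: str) -> np.ndarray:
        j = self._col_index(name)
        if not self.partitions:
            return np.empty(0)
        return np.concatenate([b[:, j] for b in self.partitions])

    def with_column(self, name: str, values: np.ndarray) -> "ChunkedTable":
        """Append a column, split to match the existing partitioning."""
        values = np.asarray(values, dtype=float).ravel()
        if values.size != self.n_rows:
            raise DataError(
                f"column {name!r} has {values.size} values for "
                f"{self.n_rows} rows"
            )
        out, start = [], 0
        for b in self.partitions:
            r = b.shape[0]
            out.append(np.column_stack([b, values[start : start + r]]))
            start += r
        return ChunkedTable(self.column_names + [name], out)

    def take_rows(self, indices: np.ndarray) -> "ChunkedTable":
        """Select global row indices (kept in ascending order)."""
        indices = np.sort(np.asarray(indices, dtype=int))
        out, start = [], 0
        for b in self.partitions:
            r = b.shape[0]
            local = indices[(indices >= start) & (indices < start + r)] - start
            if local.size:
                out.append(b[local])
            start += r
        return ChunkedTable(list(self.column_names), out)

    def rechunk(self, chunk_rows: int) -> "ChunkedTable":
        return ChunkedTable.from_array(
            self.materialize(), self.column_names, chunk_rows
        )

    # -- output --------------------------------------------------------------

    def write_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        path = Path(path)
        with open(path, "w", newline="\n") as fh:
            fh.write("\t".join(self.column_names) + "\n")
            for block in self.iter_partitions():
                for row in block:
                    fh.write(
                        "\t".join(float_format % v for v in row) + "\n"
                    )


# ---------------------------------------------------------------------------
# Moment accumulation (map-reduce sufficient statistics)
# ---------------------------------------------------------------------------


@dataclass
class MomentAccumulator:
    """First and second moment sufficient statistics of a table.

    ``merge`` is exact, associative and commutative, so moments may be
    accumulated per partition in any order or grouping.
    """

    n: int
    sum_x: np.ndarray
    sum_xxT: np.ndarray

    @classmethod
    def empty(cls, p: int) -> "MomentAccumulator":
        return cls(0, np.zeros(p), np.zeros((p, p)))

    @classmethod
    def from_partition(cls, block: np.ndarray) -> "MomentAccumulator":
        block = np.asarray(block, dtype=float)
        return cls(block.shape[0], block.sum(axis=0), block.T @ block)

    def merge(self, other: "MomentAccumulator") -> "MomentAccumulator":
        return MomentAccumulator(
            self.n + other.n,
            self.sum_x + other.sum_x,
            self.sum_xxT + other.sum_xxT,
        )

    @property
    def mean(self) -> np.ndarray:
        return self.sum_x / self.n

    @property
    def covariance(self) -> np.ndarray:
        """Population covariance (divide by n)."""
        m = self.mean
        return self.sum_xxT / self.n - np.outer(m, m)

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance).copy()


def column_moments(table: ChunkedTable) -> MomentAccumulator:
    """Exact streamed column means and cross-products of ``table``."""
    acc = MomentAccumulator.empty(table.n_columns)
    for block in table.iter_partitions():
        acc = acc.merge(MomentAccumulator.from_partition(block))
    if acc.n == 0:
        raise DataError("cannot compute moments of an empty table")
    return acc


def standardize(table: ChunkedTable, with_std: bool = True) -> ChunkedTable:
    """Center (and optionally scale to unit variance) every column.

    Two-pass streaming: one reduction for the moments, one map for the
    transform. Variance uses the population convention so that the moments of
    the output have exactly unit diagonal.
    """
    acc = column_moments(table)
    mean = acc.mean
    if with_std:
        var = acc.variances
        bad = np.flatnonzero(var <= 0)
        if bad.size:
            names = [table.column_names[j] for j in bad]
            raise DataError(
                f"cannot scale zero-variance column(s): {names}"
            )
        scale = np.sqrt(var)
    else:
        scale = np.ones(table.n_columns)
    return ChunkedTable(
        list(table.column_names),
        [(b - mean) / scale for b in table.iter_partitions()],
    )


# ---------------------------------------------------------------------------
# Class-balanced sampling
# ---------------------------------------------------------------------------


def class_counts(table: ChunkedTable, label: str) -> dict[float, int]:
    j = table._col_index(label)
    counts: dict[float, int] = {}
    for block in table.iter_partitions():
        vals, c = np.unique(block[:, j], return_counts=True)
        for v, k in zip(vals, c):
            counts[float(v)] = counts.get(float(v), 0) + int(k)
    return counts


def sample_rows(
    table: ChunkedTable, n_per_class: int, label: str, seed: int
) -> ChunkedTable:
    """Seeded uniform downsampling to ``n_per_class`` rows of every class."""
    labels = table.column(label)
    rng = np.random.default_rng(seed)
    chosen = []
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        if n_per_class > idx.size:
            raise DataError(
                f"class {value!r} has {idx.size} rows, fewer than "
                f"n_per_class={n_per_class}"
            )
        chosen.append(rng.choice(idx, size=n_per_class, replace=False))
    return table.take_rows(np.concatenate(chosen))


def balanced_downsample(
    table: ChunkedTable, label: str, seed: int
) -> ChunkedTable:
    """Downsample the majority class(es) so all classes have equal counts."""
    counts = class_counts(table, label)
    if not counts:
        raise DataError("label column is empty")
    n_min = min(counts.values())
    if len(set(counts.values())) > 1:
        logger.info(
            "balancing %s: downsampling classes %s to %d rows each",
            label, counts, n_min,
        )
    return sample_rows(table, n_min, label, seed)


# ---------------------------------------------------------------------------
# TSV input
# ---------------------------------------------------------------------------


def read_feature_names(path: str | Path) -> list[str]:
    """Read a one-column TSV of feature names (one name per line)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature file not found: {path}")
    names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not names:
        raise DataError(f"feature file is empty: {path}")
    return names


def read_tsv(
    path: str | Path,
    columns: Sequence[str] | None = None,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> ChunkedTable:
    """Read a header-bearing TSV into a :class:`ChunkedTable`.

    Only the requested ``columns`` are kept (all, in header order, when
    omitted). Rows with missing values in the selected columns are dropped
    with a logged count; a non-numeric cell is an error naming its row and
    column. Tolerates LF and CRLF line endings.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")

    header = pd.read_csv(path, sep="\t", nrows=0).columns.tolist()
    if columns is None:
        columns = header
    missing = [c for c in columns if c not in header]
    if missing:
        raise DataError(
            f"column(s) {missing} not found in {path} "
            f"(header has {header})"
        )

    blocks: list[np.ndarray] = []
    n_dropped = 0
    row_offset = 0
    reader = pd.read_csv(
        path, sep="\t", usecols=list(columns), chunksize=chunk_rows,
        dtype=object,
    )
    for chunk in reader:
        chunk = chunk[list(columns)]
        numeric = chunk.apply(lambda s: pd.to_numeric(s, errors="coerce"))
        bad = numeric.isna() & chunk.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise DataError(
                f"non-numeric value {chunk.iloc[r, c]!r} at row "
                f"{row_offset + r + 1}, column {columns[c]!r} of {path}"
            )
        na_rows = numeric.isna().any(axis=1).to_numpy()
        n_dropped += int(na_rows.sum())
        kept = numeric.to_numpy(dtype=float)[~na_rows]
        if kept.shape[0]:
            blocks.append(kept)
        row_offset += len(chunk)
    if row_offset == 0:
        raise DataError(f"{path} contains a header but no data rows")
    if n_dropped:
        logger.warning(
            "dropped %d row(s) with missing values from %s", n_dropped, path
        )
    if not blocks:
        raise DataError(f"all rows of {path} had missing values")
    return ChunkedTable(list(columns), blocks)
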