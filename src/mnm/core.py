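"""Core data structures: genomic bin indices and cell x bin copy-number matrices.

Copy numbers are stored as floats so that a single ``NaN`` marker can denote
missing values; observed values are integer-like but medians and imputed
values may be fractional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_SEX_CHROMS = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def chrom_sort_key(chrom: str):
    """Natural ordering key so that chr2 sorts before chr10."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def is_autosome(chrom: str) -> bool:
    return chrom not in _SEX_CHROMS


class BinIndex:
    """Ordered, non-overlapping genomic windows (0-based half-open)."""

    __slots__ = ("chroms", "starts", "ends")

    def __init__(self, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]):
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms, starts and ends must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("every bin must satisfy end > start")
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        keys = [chrom_sort_key(c) for c in self.chroms]
        for i in range(1, len(self)):
            if keys[i] < keys[i - 1]:
                raise ValueError("bins are not sorted by chromosome")
            if keys[i] == keys[i - 1]:
                if self.starts[i] < self.ends[i - 1]:
                    raise ValueError(
                        f"bins overlap or are unsorted at index {i} "
                        f"({self.chroms[i]}:{self.starts[i]})"
                    )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "BinIndex":
        recs = sorted(records, key=lambda r: (chrom_sort_key(r[0]), r[1]))
        if not recs:
            raise ValueError("cannot build an empty BinIndex")
        chroms, starts, ends = zip(*recs)
        return cls(chroms, starts, ends)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "BinIndex":
        records = []
        for lab in labels:
            m = _REGION_RE.match(str(lab).strip())
            if m is None:
                raise ValueError(f"malformed region header: {lab!r}")
            records.append((m["chrom"], int(m["start"]), int(m["end"])))
        return cls.from_records(records)

    # -- views -------------------------------------------------------------
    def labels(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def autosomal_mask(self) -> np.ndarray:
        return np.array([is_autosome(c) for c in self.chroms], dtype=bool)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, index) -> "BinIndex":
        return BinIndex(self.chroms[index], self.starts[index], self.ends[index])

    def __len__(self) -> int:
        return len(self.chroms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinIndex):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    def __repr__(self) -> str:
        return f"BinIndex({len(self)} bins, {len(self.chromosomes())} chromosomes)"


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int) -> BinIndex:
    """Tile each chromosome with fixed windows; the last one may be shorter."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    records = []
    for chrom in sorted(chrom_sizes, key=chrom_sort_key):
        size = int(chrom_sizes[chrom])
        for start in range(0, size, bin_size):
            records.append((chrom, start, min(start + bin_size, size)))
    return BinIndex.from_records(records)


@dataclass
class CopyNumberMatrix:
    """Cells x genomic bins of copy numbers, with NaN for missing entries."""

    cells: np.ndarray
    bins: BinIndex
    values: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cells), len(self.bins)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.bins)} bins"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("copy numbers must be >= 0 or missing")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def copy(self) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.cells.copy(), self.bins, self.values.copy())

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def select_cells(self, index) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.cells[index], self.bins, self.values[index])

    def select_bins(self, index) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.cells, self.bins.subset(index), self.values[:, index])

    def autosomal(self) -> "CopyNumberMatrix":
        return self.select_bins(self.bins.autosomal_mask())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cells), columns=self.bins.labels())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CopyNumberMatrix":
        bins = BinIndex.from_labels(frame.columns)
        # from_labels sorts; re-order the columns to match
        order = {lab: i for i, lab in enumerate(frame.columns)}
        col_idx = [order[lab] for lab in bins.labels()]
        values = frame.to_numpy(dtype=np.float64)[:, col_idx]
        return cls(np.asarray(frame.index, dtype=object), bins, values)
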