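"""Reading, writing and rebinning single-cell copy-number tables.

Two layouts are supported:

* ``bed`` — tab-separated ``chrom  start  end  copy_number  cell_id`` rows
  (no header, or a leading ``#`` comment line);
* ``matrix`` — TSV/CSV with cell identifiers in the first column and
  ``chr:start-end`` region strings as the remaining column headers.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinIndex, CopyNumberMatrix, chrom_sort_key, make_bins

_BED_COLUMNS = ["chrom", "start", "end", "copy_number", "cell_id"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> ordered dict."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["chrom", "length"], dtype={"chrom": str})
    return {str(c): int(l) for c, l in zip(table["chrom"], table["length"])}


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_cn(path, layout: str = "bed") -> CopyNumberMatrix:
    """Load a copy-number table in either accepted layout."""
    if layout == "bed":
        return _read_bed(path)
    if layout == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown layout {layout!r} (expected 'bed' or 'matrix')")


def _read_bed(path) -> CopyNumberMatrix:
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=_BED_COLUMNS,
                        dtype={"chrom": str, "cell_id": str})
    table["copy_number"] = pd.to_numeric(table["copy_number"], errors="coerce")
    table["start"] = table["start"].astype(np.int64)
    table["end"] = table["end"].astype(np.int64)

    region = list(zip(table["chrom"], table["start"], table["end"]))
    table = table.assign(_region=region)
    conflicts = (
        table.dropna(subset=["copy_number"])
        .groupby(["cell_id", "_region"])["copy_number"]
        .nunique()
    )
    if (conflicts > 1).any():
        cell, reg = conflicts[conflicts > 1].index[0]
        raise ValueError(f"conflicting copy numbers for cell {cell!r} at {reg}")
    table = table.drop_duplicates(subset=["cell_id", "_region"], keep="first")

    bins = BinIndex.from_records(set(region))
    bin_pos = {rec: i for i, rec in
               enumerate(zip(bins.chroms, bins.starts, bins.ends))}
    cells = list(dict.fromkeys(table["cell_id"]))
    cell_pos = {c: i for i, c in enumerate(cells)}

    values = np.full((len(cells), len(bins)), np.nan)
    rows = table["cell_id"].map(cell_pos).to_numpy()
    cols = np.array([bin_pos[r] for r in table["_region"]])
    values[rows, cols] = table["copy_number"].to_numpy()
    return CopyNumberMatrix(np.asarray(cells, dtype=object), bins, values)


def _read_matrix(path) -> CopyNumberMatrix:
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame.index = frame.index.astype(str)
    return CopyNumberMatrix.from_frame(frame)


def write_cn(matrix: CopyNumberMatrix, path, layout: str = "bed") -> None:
    if layout == "matrix":
        matrix.to_frame().to_csv(path, sep="\t", index_label="cell_id")
        return
    if layout != "bed":
        raise ValueError(f"unknown layout {layout!r}")
    n_cells, n_bins = matrix.values.shape
    table = pd.DataFrame({
        "chrom": np.tile(matrix.bins.chroms, n_cells),
        "start": np.tile(matrix.bins.starts, n_cells),
        "end": np.tile(matrix.bins.ends, n_cells),
        "copy_number": matrix.values.ravel(),
        "cell_id": np.repeat(matrix.cells, n_bins),
    }).dropna(subset=["copy_number"])
    if (table["copy_number"] % 1 == 0).all():
        table["copy_number"] = table["copy_number"].astype(np.int64)
    table.to_csv(path, sep="\t", header=False, index=False)


def rebin(matrix: CopyNumberMatrix, bin_size: int,
          chrom_sizes: dict[str, int]) -> CopyNumberMatrix:
    """Rearrange arbitrary input bins into fixed non-overlapping windows.

    Each output value is the per-cell median of input values whose bins
    overlap the window by at least 50% of the *input* bin's length; windows
    with no qualifying input are missing.  An input bin split exactly 50/50
    between two windows contributes to both.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    for chrom in matrix.bins.chromosomes():
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} missing from chromosome sizes")

    windows = make_bins(chrom_sizes, bin_size)
    win_offset: dict[str, int] = {}
    win_count: dict[str, int] = {}
    for i, chrom in enumerate(windows.chroms):
        win_offset.setdefault(chrom, i)
        win_count[chrom] = win_count.get(chrom, 0) + 1

    # input bin -> qualifying window columns
    members: list[list[int]] = [[] for _ in range(len(windows))]
    for j in range(matrix.n_bins):
        chrom = matrix.bins.chroms[j]
        start = int(matrix.bins.starts[j])
        end = int(matrix.bins.ends[j])
        length = end - start
        first = start // bin_size
        last = (end - 1) // bin_size
        for w in range(first, last + 1):
            if w >= win_count[chrom]:
                break
            col = win_offset[chrom] + w
            ws, we = windows.starts[col], windows.ends[col]
            overlap = min(end, we) - max(start, ws)
            if 2 * overlap >= length:
                members[col].append(j)

    out = np.full((matrix.n_cells, len(windows)), np.nan)
    for col, cols_in in enumerate(members):
        if not cols_in:
            continue
        sub = matrix.values[:, cols_in]
        with np.errstate(all="ignore"):
            out[:, col] = np.nanmedian(sub, axis=1)
    return CopyNumberMatrix(matrix.cells, windows, out)


@dataclass
class RemovedBins:
    """Book-keeping to reinsert fully-missing windows after processing."""

    positions: np.ndarray  # column indices in the original matrix
    bins: BinIndex


def drop_empty_bins(matrix: CopyNumberMatrix) -> tuple[CopyNumberMatrix, RemovedBins]:
    empty = np.all(np.isnan(matrix.values), axis=0)
    removed = RemovedBins(np.flatnonzero(empty), matrix.bins.subset(empty)) \
        if empty.any() else RemovedBins(np.array([], dtype=int), None)
    if not empty.any():
        return matrix, removed
    return matrix.select_bins(~empty), removed


def restore_empty_bins(matrix: CopyNumberMatrix, removed: RemovedBins) -> CopyNumberMatrix:
    if removed.positions.size == 0:
        return matrix
    n_total = matrix.n_bins + removed.positions.size
    values = np.full((matrix.n_cells, n_total), np.nan)
    keep = np.setdiff1d(np.arange(n_total), removed.positions)
    values[:, keep] = matrix.values

    chroms = np.empty(n_total, dtype=object)
    starts = np.empty(n_total, dtype=np.int64)
    ends = np.empty(n_total, dtype=np.int64)
    chroms[keep], starts[keep], ends[keep] = (
        matrix.bins.chroms, matrix.bins.starts, matrix.bins.ends)
    chroms[removed.positions] = removed.bins.chroms
    starts[removed.positions] = removed.bins.starts
    ends[removed.positions] = removed.bins.ends
    return CopyNumberMatrix(matrix.cells, BinIndex(chroms, starts, ends), values)
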