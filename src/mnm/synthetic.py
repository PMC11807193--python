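"""Synthetic single-cell copy-number cohorts.

Generates clonal populations with integer karyotypes, sporadic +/-1 noise,
replicating (S-phase) cells whose bins double in a fixed replication order,
random missingness, and barcode read counts drawn from a two-component
log-normal mixture.  Everything is driven by explicit seeds so that
downstream modules can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import BinIndex, CopyNumberMatrix, make_bins

#: small genome used by default in tests: 10 chromosomes x 10 Mb
DEFAULT_CHROM_SIZES = {f"chr{i}": 10_000_000 for i in range(1, 11)}


@dataclass(frozen=True)
class CloneSpec:
    """A clonal population: per-chromosome karyotype plus optional segments.

    ``karyotype`` maps chromosome -> integer copy number; chromosomes not
    listed fall back to ``default_ploidy`` (set it to ``None`` to make an
    incomplete karyotype an error).  ``segments`` are sub-chromosomal
    overrides ``(chrom, start, end, copy_number)`` applied on top.
    """

    name: str
    karyotype: Mapping[str, int] = field(default_factory=dict)
    n_cells: int = 1
    noise_rate: float = 0.0
    default_ploidy: Optional[int] = 2
    segments: tuple = ()

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be within [0, 1]")
        for cn in self.karyotype.values():
            if int(cn) != cn or cn < 0:
                raise ValueError("karyotype copy numbers must be integers >= 0")

    def profile(self, bins: BinIndex) -> np.ndarray:
        """Expand the karyotype to a per-bin integer copy-number vector."""
        base = np.empty(len(bins), dtype=np.int64)
        for j, chrom in enumerate(bins.chroms):
            if chrom in self.karyotype:
                base[j] = self.karyotype[chrom]
            elif self.default_ploidy is not None:
                base[j] = self.default_ploidy
            else:
                raise KeyError(f"karyotype of clone {self.name!r} does not cover {chrom}")
        for chrom, start, end, cn in self.segments:
            hit = (bins.chroms == chrom) & (bins.starts < end) & (bins.ends > start)
            base[hit] = cn
        return base


@dataclass(frozen=True)
class RTSpec:
    """Replication order of bins, earliest first (a permutation of bin indices)."""

    rt_order: np.ndarray

    def __post_init__(self):
        order = np.asarray(self.rt_order, dtype=np.int64)
        object.__setattr__(self, "rt_order", order)
        if order.size == 0:
            raise ValueError("rt_order covers no bins")
        if not np.array_equal(np.sort(order), np.arange(order.size)):
            raise ValueError("rt_order must be a permutation of all bin indices")

    @classmethod
    def random(cls, n_bins: int, seed: int) -> "RTSpec":
        rng = np.random.default_rng(seed)
        return cls(rng.permutation(n_bins))


def _apply_noise(values: np.ndarray, noise_rate: float, rng: np.random.Generator) -> None:
    """In-place sporadic +/-1 alterations; each bin flips independently."""
    if noise_rate <= 0:
        return
    flip = rng.random(values.shape) < noise_rate
    signs = rng.choice([-1, 1], size=values.shape)
    values += np.where(flip, signs, 0)
    np.clip(values, 0, None, out=values)


def make_g1_population(
    clones: Sequence[CloneSpec], bins: BinIndex, seed: int
) -> tuple[CopyNumberMatrix, np.ndarray]:
    """Non-replicating cells for each clone; returns the matrix + clone labels."""
    if not clones:
        raise ValueError("empty clone list")
    rng = np.random.default_rng(seed)
    rows, cells, labels = [], [], []
    for clone in clones:
        base = clone.profile(bins)
        for i in range(clone.n_cells):
            profile = base.astype(np.float64)
            _apply_noise(profile, clone.noise_rate, rng)
            rows.append(profile)
            cells.append(f"{clone.name}_g1_{i}")
            labels.append(clone.name)
    matrix = CopyNumberMatrix(np.asarray(cells, dtype=object), bins, np.vstack(rows))
    return matrix, np.asarray(labels, dtype=object)


def make_s_population(
    clone: CloneSpec,
    rt: RTSpec,
    bins: BinIndex,
    n_cells: int,
    progress_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> tuple[CopyNumberMatrix, np.ndarray]:
    """Replicating cells for one clone.

    Each cell draws a replication progress ``p`` from ``progress_range``;
    the earliest ``round(p * n_bins)`` bins of ``rt_order`` are doubled,
    the rest keep the karyotype value, then clone noise is applied.
    Returns the matrix plus the per-cell true progress (for evaluation).
    """
    lo, hi = progress_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("progress_range must lie within [0, 1]")
    if rt.rt_order.size != len(bins):
        raise ValueError("rt_order length does not match the bin index")
    rng = np.random.default_rng(seed)
    base = clone.profile(bins)
    rows, cells, progress = [], [], []
    for i in range(n_cells):
        p = lo if lo == hi else rng.uniform(lo, hi)
        n_rep = int(round(p * len(bins)))
        profile = base.astype(np.float64)
        profile[rt.rt_order[:n_rep]] *= 2
        _apply_noise(profile, clone.noise_rate, rng)
        rows.append(profile)
        cells.append(f"{clone.name}_s_{i}")
        progress.append(p)
    matrix = CopyNumberMatrix(np.asarray(cells, dtype=object), bins, np.vstack(rows))
    return matrix, np.asarray(progress)


def concat_populations(*matrices: CopyNumberMatrix) -> CopyNumberMatrix:
    """Stack cohorts that share a bin index."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.bins != first.bins:
            raise ValueError("populations are defined on different bin indices")
    return CopyNumberMatrix(
        np.concatenate([m.cells for m in matrices]),
        first.bins,
        np.vstack([m.values for m in matrices]),
    )


def mask_random(
    matrix: CopyNumberMatrix, fraction: float, seed: int
) -> tuple[CopyNumberMatrix, np.ndarray]:
    """Set exactly ``round(fraction * n_entries)`` entries missing, uniformly.

    Returns the masked matrix and the mask positions as an ``(n, 2)`` array
    of (row, column) pairs.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    if np.isnan(matrix.values).any():
        raise ValueError("matrix already contains missing values")
    rng = np.random.default_rng(seed)
    size = matrix.values.size
    n_mask = int(round(fraction * size))
    flat = rng.choice(size, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat, matrix.values.shape)
    masked = matrix.copy()
    masked.values[rows, cols] = np.nan
    return masked, np.column_stack([rows, cols])


def make_barcode_counts(
    n_valid: int,
    n_invalid: int,
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Barcode read counts from a two-component log-normal mixture.

    Component 1 (``mu1``, ``sigma1``) is the lower, invalid population;
    component 2 is the valid one.  Returns columns
    ``barcode, read_count, valid``.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigma parameters must be positive")
    if mu2 <= mu1:
        raise ValueError("the valid component must have the larger location (mu2 > mu1)")
    rng = np.random.default_rng(seed)
    invalid = rng.lognormal(mu1, sigma1, size=n_invalid)
    valid = rng.lognormal(mu2, sigma2, size=n_valid)
    counts = np.concatenate([invalid, valid]).round().astype(np.int64)
    truth = np.concatenate([np.zeros(n_invalid, bool), np.ones(n_valid, bool)])
    barcodes = np.array([f"BC{i:06d}" for i in range(counts.size)], dtype=object)
    return pd.DataFrame({"barcode": barcodes, "read_count": counts, "valid": truth})


# ---------------------------------------------------------------------------
# cohort-level convenience (used by the `mnm simulate` command)


def simulate_cohort(config: dict) -> tuple[CopyNumberMatrix, pd.DataFrame]:
    """Build a mixed G1/S cohort from a config dictionary.

    Config keys: ``seed``, ``bin_size``, ``chrom_sizes`` (mapping),
    ``progress_range`` and ``clones`` — a list of mappings with ``name``,
    ``n_g1``, ``n_s``, optional ``karyotype``/``segments``/``noise_rate``.
    Returns the matrix and a truth table (cell_id, clone, phase, progress).
    """
    seed = int(config.get("seed", 0))
    chrom_sizes = config.get("chrom_sizes") or DEFAULT_CHROM_SIZES
    bin_size = int(config.get("bin_size", 100_000))
    bins = make_bins(chrom_sizes, bin_size)
    progress_range = tuple(config.get("progress_range", (0.05, 0.95)))
    rt = RTSpec.random(len(bins), seed=seed + 101)

    matrices, truth_rows = [], []
    for ci, spec in enumerate(config["clones"]):
        clone = CloneSpec(
            name=spec["name"],
            karyotype={str(k): int(v) for k, v in (spec.get("karyotype") or {}).items()},
            n_cells=max(int(spec.get("n_g1", 0)), 1),
            noise_rate=float(spec.get("noise_rate", 0.0)),
            segments=tuple(tuple(s) for s in spec.get("segments", ())),
        )
        n_g1 = int(spec.get("n_g1", 0))
        n_s = int(spec.get("n_s", 0))
        if n_g1 > 0:
            g1, _ = make_g1_population([clone], bins, seed=seed + 13 * ci)
            matrices.append(g1)
            truth_rows += [(c, clone.name, "G1", np.nan) for c in g1.cells]
        if n_s > 0:
            s, progress = make_s_population(
                clone, rt, bins, n_s, progress_range, seed=seed + 13 * ci + 7)
            matrices.append(s)
            truth_rows += [(c, clone.name, "S", p) for c, p in zip(s.cells, progress)]
    if not matrices:
        raise ValueError("config produced no cells")
    matrix = concat_populations(*matrices)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "clone", "phase", "progress"])
    return matrix, truth
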