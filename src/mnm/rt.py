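"""Replication-timing utilities.

Binarise S-phase copy numbers against a non-replicating baseline, aggregate
binary calls into pseudo-bulk RT profiles, compare profiles with a Spearman
correlation atlas ordered by Ward-linkage clustering, and test group
separation of 2-D trajectory coordinates with a label-permutation test.

The binarisation threshold (copy ratio >= 1.5, the midpoint between an
unreplicated x1 and a replicated x2 bin) is a deliberate simplification of
the upstream per-cell thresholding and is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .core import BinIndex, CopyNumberMatrix

BINARIZE_RATIO = 1.5


@dataclass
class BinaryRTMatrix:
    """S cells x bins: 1 = replicated, 0 = unreplicated, NaN = missing."""

    cells: np.ndarray
    bins: BinIndex
    values: np.ndarray

    def progress(self) -> np.ndarray:
        """Fraction of non-missing bins replicated, per cell."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)


@dataclass
class RTProfile:
    """Per-bin pseudo-bulk RT in [0, 1] (1 = earliest); NaN where undefined."""

    bins: BinIndex
    values: np.ndarray
    name: str = ""
    n_cells: int = 0


def binarize_s_cells(
    s_matrix: CopyNumberMatrix,
    g1_median_profile: np.ndarray,
    ratio: float = BINARIZE_RATIO,
) -> BinaryRTMatrix:
    """A bin is replicated iff its copy number is >= ``ratio`` x baseline."""
    baseline = np.asarray(g1_median_profile, dtype=float)
    if baseline.size != s_matrix.n_bins:
        raise ValueError("baseline length does not match the bin index")
    observed = ~np.isnan(s_matrix.values)
    bad = (baseline <= 0) & observed.any(axis=0)
    if bad.any():
        raise ValueError("baseline is zero on a bin with S-phase data")
    with np.errstate(divide="ignore", invalid="ignore"):
        binary = np.where(observed,
                          (s_matrix.values / baseline >= ratio).astype(float),
                          np.nan)
    return BinaryRTMatrix(s_matrix.cells, s_matrix.bins, binary)


def pseudobulk_rt(binary: BinaryRTMatrix, name: str = "") -> RTProfile:
    """Per bin: fraction of informative S cells in which the bin is replicated."""
    if binary.values.shape[0] < 1:
        raise ValueError("need at least one S cell")
    informative = (~np.isnan(binary.values)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.nansum(binary.values, axis=0) / informative
    values[informative == 0] = np.nan
    return RTProfile(binary.bins, values, name=name, n_cells=binary.values.shape[0])


def correlate_profiles(
    profiles: Sequence[RTProfile],
) -> tuple[pd.DataFrame, list[int]]:
    """Pairwise Spearman correlation over shared bins + Ward leaf order.

    Correlations use bins defined in both profiles; the dendrogram order
    comes from Ward-linkage clustering (the squared-distance variant) on
    ``1 - correlation``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    names = [p.name or f"profile_{i}" for i, p in enumerate(profiles)]
    n = len(profiles)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = profiles[i].values, profiles[j].values
            shared = ~np.isnan(a) & ~np.isnan(b)
            if shared.sum() < 3:
                raise ValueError(
                    f"profiles {names[i]!r} and {names[j]!r} share fewer than 3 bins")
            rho = spearmanr(a[shared], b[shared]).statistic
            corr[i, j] = corr[j, i] = rho
    frame = pd.DataFrame(corr, index=names, columns=names)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    order = list(leaves_list(linkage(dist, method="ward")))
    return frame, order


def trajectory_permutation_test(
    coords: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "literal",
) -> dict:
    """Permutation test for group separation of 2-D trajectory coordinates.

    ``coords`` needs columns ``coord1, coord2, group``.  The default
    ("literal") statistic sums, over groups, the absolute difference
    between the group's mean first and mean second coordinate; the
    "centroid" alternative sums pairwise between-group centroid distances.
    p = (#(permuted >= observed) + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = coords["group"].to_numpy()
    uniq, labels = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(labels)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two points")
    xy = coords[["coord1", "coord2"]].to_numpy(dtype=float)

    def stat(lab: np.ndarray) -> float:
        mx = np.array([xy[lab == g, 0].mean() for g in range(uniq.size)])
        my = np.array([xy[lab == g, 1].mean() for g in range(uniq.size)])
        if statistic == "literal":
            return float(np.sum(np.abs(mx - my)))
        if statistic == "centroid":
            cent = np.column_stack([mx, my])
            d = 0.0
            for i in range(uniq.size):
                for j in range(i + 1, uniq.size):
                    d += float(np.linalg.norm(cent[i] - cent[j]))
            return d
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    # the statistic can tie exactly with the observed value for many
    # permutations (e.g. equal-size groups); a tiny tolerance keeps the
    # ">=" tie-counting stable against floating-point noise
    tol = 1e-9 * max(1.0, abs(observed))
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= observed - tol:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)
    return {
        "observed": observed,
        "p_value": float(p_value),
        "n_perm": int(n_perm),
        "statistic": statistic,
        "groups": [str(g) for g in uniq],
    }


def write_bedgraph(profile: RTProfile, path) -> None:
    """bedGraph of the pseudo-bulk RT values (undefined bins are skipped)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.name or "RT"}"\n')
        for chrom, start, end, v in zip(
            profile.bins.chroms, profile.bins.starts, profile.bins.ends, profile.values
        ):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
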