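"""Missing copy-number imputation.

The main method is a distance-weighted k-nearest-neighbour scheme: cell-to-
cell distances are Euclidean over the bins observed in both cells, rescaled
by ``sqrt(n_bins / n_jointly_observed)``, and each missing entry is filled
with the inverse-distance-weighted mean of the k nearest cells that have an
observed value at that bin.  Median and random baselines are provided for
comparison, along with the accuracy / similarity / invariance evaluation
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core import CopyNumberMatrix


@dataclass
class ImputationResult:
    matrix: CopyNumberMatrix
    imputed_positions: np.ndarray  # (n, 2) row/column pairs
    k: int
    skipped_bins: np.ndarray = None  # bins with no observed value anywhere


@dataclass
class ImputationMetrics:
    accuracy: float    # % of imputed values identical (after rounding) to the original
    similarity: float  # % of imputed values within +/-1 of the original
    invariance: float  # % of all matrix values unchanged


def knn_impute(matrix: CopyNumberMatrix, k: int = 5) -> ImputationResult:
    """Fill every missing entry from the k nearest cells observed at that bin.

    A neighbour at distance zero short-circuits the weighted mean: the
    imputed value is the plain mean of the zero-distance neighbours among
    the selected k.  Distance ties are broken by cell order.
    """
    values = matrix.values
    missing = np.isnan(values)
    out = values.copy()
    if not missing.any():
        return ImputationResult(
            CopyNumberMatrix(matrix.cells, matrix.bins, out),
            np.empty((0, 2), dtype=int), k, np.array([], dtype=int))
    if matrix.n_cells < k + 1:
        raise ValueError(f"need at least {k + 1} cells for k={k} imputation")

    # pairwise missing-aware distances, scaled by sqrt(total/observed)
    dist = nan_euclidean_distances(values)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # pairs sharing no observed bin

    imputed_rows: list[np.ndarray] = []
    imputed_cols: list[np.ndarray] = []
    skipped: list[int] = []
    warned_few = False
    for j in np.flatnonzero(missing.any(axis=0)):
        obs = np.flatnonzero(~missing[:, j])
        if obs.size == 0:
            skipped.append(j)
            continue
        miss = np.flatnonzero(missing[:, j])
        kk = min(k, obs.size)
        if obs.size < k and not warned_few:
            warnings.warn(
                f"fewer than k={k} candidate neighbours at some bins; using all available",
                RuntimeWarning)
            warned_few = True

        d = dist[np.ix_(miss, obs)]
        # stable sort: distance ties are broken by cell order
        part = np.argsort(d, axis=1, kind="stable")[:, :kk]
        dk = np.take_along_axis(d, part, axis=1)
        vk = values[obs[part], j]

        zero = dk == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 / dk
            w[~np.isfinite(dk)] = 0.0  # neighbours with no shared bins
            weighted = (w * vk).sum(axis=1) / w.sum(axis=1)
        est = np.where(
            zero.any(axis=1),
            np.nansum(np.where(zero, vk, 0.0), axis=1) / np.maximum(zero.sum(axis=1), 1),
            np.where(np.isfinite(weighted), weighted, vk.mean(axis=1)),
        )
        out[miss, j] = est
        imputed_rows.append(miss)
        imputed_cols.append(np.full(miss.size, j))

    if imputed_rows:
        positions = np.column_stack(
            [np.concatenate(imputed_rows), np.concatenate(imputed_cols)])
    else:
        positions = np.empty((0, 2), dtype=int)
    result = CopyNumberMatrix(matrix.cells, matrix.bins, out)
    return ImputationResult(result, positions, k, np.asarray(skipped, dtype=int))


def baseline_impute(matrix: CopyNumberMatrix, method: str, seed: int = 0) -> ImputationResult:
    """Comparison baselines: per-bin ``median`` or matrix-wide ``random`` draw."""
    values = matrix.values
    missing = np.isnan(values)
    out = values.copy()
    rows, cols = np.nonzero(missing)
    skipped = np.flatnonzero(missing.all(axis=0))

    if method == "median":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bin_median = np.nanmedian(values, axis=0)
        fill = bin_median[cols]
        ok = ~np.isnan(fill)
        out[rows[ok], cols[ok]] = fill[ok]
        positions = np.column_stack([rows[ok], cols[ok]])
    elif method == "random":
        rng = np.random.default_rng(seed)
        pool = values[~missing]
        if pool.size == 0:
            raise ValueError("no observed values to draw from")
        out[rows, cols] = rng.choice(pool, size=rows.size, replace=True)
        positions = np.column_stack([rows, cols])
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return ImputationResult(CopyNumberMatrix(matrix.cells, matrix.bins, out),
                            positions, 0, skipped)


def evaluate_imputation(
    original: CopyNumberMatrix | np.ndarray,
    mask_positions: np.ndarray,
    imputed: CopyNumberMatrix | np.ndarray,
) -> ImputationMetrics:
    """Accuracy / similarity over the masked entries, invariance matrix-wide.

    Imputed values are rounded to the nearest integer before comparison
    (observed copy numbers are integer-valued).
    """
    orig = original.values if isinstance(original, CopyNumberMatrix) else np.asarray(original)
    imp = imputed.values if isinstance(imputed, CopyNumberMatrix) else np.asarray(imputed)
    if orig.shape != imp.shape:
        raise ValueError("original and imputed matrices differ in shape")
    mask_positions = np.asarray(mask_positions)
    rows, cols = mask_positions[:, 0], mask_positions[:, 1]

    truth = orig[rows, cols]
    filled = np.round(imp[rows, cols])
    known = ~np.isnan(filled)
    exact = np.sum(known & (filled == truth))
    close = np.sum(known & (np.abs(filled - truth) <= 1.0))

    n_masked = rows.size
    accuracy = 100.0 * exact / n_masked
    similarity = 100.0 * close / n_masked
    invariance = 100.0 * (orig.size - n_masked + exact) / orig.size
    return ImputationMetrics(accuracy, similarity, invariance)


def impute_benchmark(
    matrix: CopyNumberMatrix,
    fractions,
    seed: int,
    k: int = 5,
    methods=("knn", "median", "random"),
):
    """Mask/impute/evaluate over a grid of masking fractions.

    Returns a tidy DataFrame (fraction, method, accuracy, similarity,
    invariance), mirroring the masking-evaluation simulation.
    """
    import pandas as pd

    from .synthetic import mask_random

    records = []
    for fi, fraction in enumerate(fractions):
        masked, positions = mask_random(matrix, fraction, seed=seed + fi)
        for method in methods:
            if method == "knn":
                res = knn_impute(masked, k=k)
            else:
                res = baseline_impute(masked, method, seed=seed + fi)
            m = evaluate_imputation(matrix, positions, res.matrix)
            records.append((fraction, method, m.accuracy, m.similarity, m.invariance))
    return pd.DataFrame(
        records, columns=["fraction", "method", "accuracy", "similarity", "invariance"])
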