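"""Genomic subpopulation discovery and S-cell matching.

Non-replicating cells (plus five artificial calibration cells spanning
haploid to pentaploid) are embedded to 2-D with UMAP and clustered with
DBSCAN, whose epsilon is derived from the embedding's coordinate ranges:

    epsilon = clamp((range(UMAP1) / range(UMAP2)) * 1.25, 1.25, 2)

The embedding/clustering round is repeated with six auxiliary seeds and the
modal cluster count wins.  Near-identical clusters (>= 98.5% identical
rounded median profiles) are merged iteratively, then replicating cells are
matched to the non-replicating groups by majority vote of their nearest
neighbours in a 10-D UMAP embedding of all cells.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .core import CopyNumberMatrix

DEFAULT_SEED = 18671107
CALIBRATION_PLOIDIES = (1, 2, 3, 4, 5)
EPSILON_BOUNDS = (1.25, 2.0)
MIN_SUBPOP_CELLS = 10
MERGE_IDENTITY = 0.985


@dataclass
class EmbeddingResult:
    coords: np.ndarray            # (n_cells [+ calibration], d)
    seed: int
    calibration_mask: np.ndarray  # True on the appended calibration rows
    cells: np.ndarray


@dataclass
class SubpopulationAssignment:
    cells: np.ndarray
    labels: np.ndarray                       # subpopulation id per cell, 1..K
    medians: dict[int, np.ndarray]           # per-subpopulation median profile
    votes: list[tuple[int, int]] = field(default_factory=list)  # (seed, K) per run
    features: Optional[np.ndarray] = None    # cell x bin values used (autosomal)
    epsilon: Optional[float] = None
    min_samples: Optional[int] = None
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_subpopulations(self) -> int:
        return len(self.medians)


def epsilon_from_embedding(coords: np.ndarray, literal_denominator: bool = False) -> float:
    """DBSCAN epsilon from the 2-D embedding's coordinate ranges.

    ``literal_denominator=True`` reproduces the printed cross-axis form
    ``max(UMAP2) - min(UMAP1)`` instead of the second axis' own range.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two points")
    r1 = float(coords[:, 0].max() - coords[:, 0].min())
    if literal_denominator:
        denom = float(coords[:, 1].max() - coords[:, 0].min())
    else:
        denom = float(coords[:, 1].max() - coords[:, 1].min())
    if denom == 0:
        raise ValueError("zero range on the second embedding coordinate")
    lo, hi = EPSILON_BOUNDS
    return float(min(max(r1 / denom * 1.25, lo), hi))


def _umap_embed(values: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    import umap  # deferred: slow import

    n_neighbors = int(min(15, max(2, values.shape[0] - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=n_neighbors,
            random_state=seed,
            n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(values), dtype=float)


def _with_calibration(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Append five constant-ploidy calibration rows; returns (stack, mask)."""
    n_bins = values.shape[1]
    calib = np.vstack([np.full(n_bins, float(p)) for p in CALIBRATION_PLOIDIES])
    mask = np.zeros(values.shape[0] + len(CALIBRATION_PLOIDIES), dtype=bool)
    mask[values.shape[0]:] = True
    return np.vstack([values, calib]), mask


def _cluster_once(values_with_calib: np.ndarray, calib_mask: np.ndarray, seed: int,
                  min_samples: int, literal_epsilon: bool,
                  ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One UMAP + DBSCAN round.  Calibration cells take part in the embedding
    (anchoring the ploidy scale) but are excluded from clustering so they
    cannot pad a small group past ``min_samples``."""
    coords = _umap_embed(values_with_calib, 2, seed)
    eps = epsilon_from_embedding(coords, literal_denominator=literal_epsilon)
    labels = np.full(coords.shape[0], -1, dtype=int)
    labels[~calib_mask] = DBSCAN(eps=eps, min_samples=min_samples).fit(
        coords[~calib_mask]).labels_
    n_clusters = len(set(labels[~calib_mask]) - {-1})
    return coords, labels, eps, n_clusters


def _attach_noise(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign DBSCAN noise points to the cluster with the nearest median
    copy-number profile.

    Attachment happens in feature space rather than on the 2-D embedding:
    borderline cells (e.g. early-S cells that slipped through the state
    classifier) land at arbitrary embedding positions, but their profiles
    remain close to their own cluster's median.
    """
    labels = labels.copy()
    clusters = sorted(set(labels) - {-1})
    if not clusters:
        raise ValueError("all points were classified as noise")
    medians = np.vstack([np.median(features[labels == c], axis=0) for c in clusters])
    noise = labels == -1
    if noise.any():
        d = np.linalg.norm(features[noise, None, :] - medians[None, :, :], axis=2)
        labels[noise] = np.asarray(clusters)[np.argmin(d, axis=1)]
    return labels


def _profile_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.round(a) == np.round(b)))


def merge_similar(
    assignment: SubpopulationAssignment, threshold: float = MERGE_IDENTITY
) -> SubpopulationAssignment:
    """Iteratively merge cluster pairs whose rounded median profiles are at
    least ``threshold`` identical, in descending-identity order, recomputing
    medians after every merge."""
    if assignment.features is None:
        raise ValueError("assignment lacks the feature matrix needed to recompute medians")
    labels = assignment.labels.copy()
    medians = dict(assignment.medians)
    merges = list(assignment.merges)

    while len(medians) > 1:
        keys = sorted(medians)
        best, best_pair = -1.0, None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                ident = _profile_identity(medians[a], medians[b])
                if ident > best:
                    best, best_pair = ident, (a, b)
        if best < threshold:
            break
        a, b = best_pair
        labels[labels == b] = a
        medians[a] = np.median(assignment.features[labels == a], axis=0)
        del medians[b]
        merges.append((a, b, best))

    # relabel compactly as 1..K in order of first appearance
    remap: dict[int, int] = {}
    new_labels = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        new_labels[i] = remap[lab]
    new_medians = {remap[k]: v for k, v in medians.items()}
    return SubpopulationAssignment(
        assignment.cells, new_labels, new_medians, assignment.votes,
        assignment.features, assignment.epsilon, assignment.min_samples, merges)


def discover_g1_subpopulations(
    matrix: CopyNumberMatrix,
    seed: int = DEFAULT_SEED,
    min_cluster_frac: float = 0.10,
    min_cluster_size: int = MIN_SUBPOP_CELLS,
    merge_threshold: float = MERGE_IDENTITY,
    n_extra_seeds: int = 6,
    attach_noise: bool = True,
    literal_epsilon: bool = False,
) -> tuple[SubpopulationAssignment, EmbeddingResult]:
    """Cluster non-replicating cells into genomic subpopulations.

    ``matrix`` must hold non-replicating cells only, already imputed.  Sex
    chromosomes are excluded from the features.  Returns the assignment and
    the retained 2-D embedding (calibration rows included, flagged).
    """
    auto = matrix.autosomal()
    X = auto.values
    if np.isnan(X).any():
        raise ValueError("run imputation first: matrix contains missing values")
    n = X.shape[0]
    if n < 20:
        raise ValueError("need at least 20 non-replicating cells")
    min_samples = max(int(round(min_cluster_frac * n)), min_cluster_size)
    if n < min_samples:
        raise ValueError("fewer cells than DBSCAN min_samples")

    stacked, calib_mask = _with_calibration(X)

    rng = np.random.default_rng(seed)
    extra = [int(s) for s in rng.integers(3, 2 ** 30, size=n_extra_seeds, endpoint=True)]
    runs = {}
    votes = []
    for s in [seed] + extra:
        runs[s] = _cluster_once(stacked, calib_mask, s, min_samples, literal_epsilon)
        votes.append((s, runs[s][3]))

    counts = Counter(k for _, k in votes)
    modal = counts.most_common()
    top = max(c for _, c in modal)
    modal_ks = {k for k, c in modal if c == top}
    if runs[seed][3] in modal_ks:
        chosen_seed = seed
    else:
        k_target = min(modal_ks)
        chosen_seed = next(s for s, k in votes if k == k_target)

    coords, db_labels, eps, _ = runs[chosen_seed]
    if attach_noise:
        labels = _attach_noise(stacked, db_labels)
    else:
        labels = db_labels
        if (labels == -1).all():
            raise ValueError("all points were classified as noise")

    cell_labels = labels[~calib_mask]
    medians = {
        int(c): np.median(X[cell_labels == c], axis=0)
        for c in sorted(set(cell_labels) - {-1})
    }
    assignment = SubpopulationAssignment(
        matrix.cells, cell_labels, medians, votes, X, eps, min_samples)
    assignment = merge_similar(assignment, merge_threshold)

    embedding = EmbeddingResult(coords, chosen_seed, calib_mask,
                                np.concatenate([matrix.cells,
                                                [f"calibration_{p}N" for p in
                                                 CALIBRATION_PLOIDIES]]))
    return assignment, embedding


def _normalize_ploidy(values: np.ndarray) -> np.ndarray:
    """Rescale each cell to mean copy number 2.

    Replicating cells carry an inflated genome-wide mean (up to 2x at the
    end of S phase); without rescaling, a mid-S cell of one clone can sit
    closer to a higher-ploidy clone's non-replicating cells than to its
    own, purely through this global shift.
    """
    means = values.mean(axis=1, keepdims=True)
    return 2.0 * values / np.where(means > 0, means, 1.0)


def match_replicating(
    full_matrix: CopyNumberMatrix,
    g1_assignment: SubpopulationAssignment,
    seed: int = DEFAULT_SEED,
    neighbor_frac: float = 0.5,
    min_neighbors: int = 5,
    normalize: bool = True,
) -> tuple[SubpopulationAssignment, EmbeddingResult]:
    """Label replicating cells with the majority subpopulation of their
    nearest non-replicating neighbours in a 10-D UMAP embedding.

    The 10-D space is anchored on the non-replicating cells (+ the
    calibration cells): UMAP is fitted on them and the replicating cells
    are transformed into that space, which places each S cell among its
    nearest non-replicating anchors instead of leaving the S manifold's
    position to the whims of a joint layout.
    """
    auto = full_matrix.autosomal()
    if np.isnan(auto.values).any():
        raise ValueError("run imputation first: matrix contains missing values")
    g1_pos = {c: i for i, c in enumerate(g1_assignment.cells)}
    is_g1 = np.array([c in g1_pos for c in auto.cells])
    if not is_g1.any():
        raise ValueError("no non-replicating cells to match against")

    full_labels = np.zeros(auto.n_cells, dtype=int)
    for i, c in enumerate(auto.cells):
        if is_g1[i]:
            full_labels[i] = g1_assignment.labels[g1_pos[c]]

    if not (~is_g1).any():  # no S cells: nothing to match
        assignment = SubpopulationAssignment(
            auto.cells, full_labels, g1_assignment.medians, g1_assignment.votes,
            auto.values, g1_assignment.epsilon, g1_assignment.min_samples,
            g1_assignment.merges)
        embedding = EmbeddingResult(np.empty((0, 10)), seed,
                                    np.zeros(0, bool), auto.cells)
        return assignment, embedding

    feats = _normalize_ploidy(auto.values) if normalize else auto.values
    g1_idx = np.flatnonzero(is_g1)
    s_idx = np.flatnonzero(~is_g1)
    anchor, _ = _with_calibration(feats[g1_idx])

    import umap  # deferred: slow import

    n_neighbors = int(min(15, max(2, anchor.shape[0] - 1)))
    # spectral initialisation needs n_components + 1 < n_points
    init = "spectral" if anchor.shape[0] > 11 else "random"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=10, n_neighbors=n_neighbors,
                            random_state=seed, n_jobs=1, init=init).fit(anchor)
        g1_coords = np.asarray(reducer.embedding_[: g1_idx.size], dtype=float)
        s_coords = np.asarray(reducer.transform(feats[s_idx]), dtype=float)

    n_g1 = g1_idx.size
    k = int(min(max(round(neighbor_frac * n_g1), min_neighbors), n_g1))
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(g1_coords)
    _, neigh = nn.kneighbors(s_coords)
    g1_labels = full_labels[g1_idx]
    for row, cell in zip(neigh, s_idx):
        votes = np.bincount(g1_labels[row])
        full_labels[cell] = int(np.argmax(votes))

    coords = np.empty((auto.n_cells, 10))
    coords[g1_idx] = g1_coords
    coords[s_idx] = s_coords
    assignment = SubpopulationAssignment(
        auto.cells, full_labels, g1_assignment.medians, g1_assignment.votes,
        auto.values, g1_assignment.epsilon, g1_assignment.min_samples,
        g1_assignment.merges)
    embedding = EmbeddingResult(coords, seed, np.zeros(auto.n_cells, bool), auto.cells)
    return assignment, embedding
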