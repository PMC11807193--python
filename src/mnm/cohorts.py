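"""Standard synthetic validation cohorts.

These builders assemble the scaled-down cohorts used by the acceptance
tests and the acceptance report: a three-karyotype cohort for classifier
training, a two-clone matrix for imputation benchmarks, and a two-population
mixture (with replicating cells) for end-to-end unmixing.

All cohorts on the same genome share one replication order per master seed:
a trained classifier is only expected to transfer between cohorts that
replicate in the same order, mirroring the conservation of the real
replication programme across human cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import make_bins
from .synthetic import (
    CloneSpec,
    RTSpec,
    concat_populations,
    make_g1_population,
    make_s_population,
)

#: 10 chromosomes x 10 Mb -> 1000 bins at 100 kb
GENOME_10x10 = {f"chr{i}": 10_000_000 for i in range(1, 11)}
#: 8 chromosomes x 16.1 Mb -> 1288 bins at 100 kb
GENOME_8x16 = {f"chr{i}": 16_100_000 for i in range(1, 9)}
BIN_SIZE = 100_000


def shared_rt(n_bins: int, seed: int) -> RTSpec:
    """The genome-wide replication order tied to a master seed."""
    return RTSpec.random(n_bins, seed=seed * 7 + 11)


def classifier_cohort(seed: int, n_g1_per_clone: int = 200, n_s_per_clone: int = 200,
                      noise: float = 0.05):
    """Three karyotypes (~600 G1 + ~600 S cells): diploid, triploid with six
    chromosome gains, and diploid with three sub-chromosomal gains.

    Returns (matrix, phases, rt).
    """
    bins = make_bins(GENOME_10x10, BIN_SIZE)
    rt = shared_rt(len(bins), seed)
    triploid_karyotype = {f"chr{i}": 3 for i in range(1, 11)}
    triploid_karyotype.update({f"chr{i}": 4 for i in (1, 3, 5, 7, 9, 10)})
    clones = [
        CloneSpec("diploid", {}, n_g1_per_clone, noise),
        CloneSpec("triploid", triploid_karyotype, n_g1_per_clone, noise),
        CloneSpec("segmental", {}, n_g1_per_clone, noise, segments=(
            ("chr2", 0, 3_000_000, 3),
            ("chr4", 2_000_000, 6_000_000, 3),
            ("chr8", 5_000_000, 9_000_000, 3),
        )),
    ]
    g1, _ = make_g1_population(clones, bins, seed=seed)
    parts, phases = [g1], ["G1"] * (3 * n_g1_per_clone)
    for i, clone in enumerate(clones):
        s, _ = make_s_population(clone, rt, bins, n_s_per_clone,
                                 (0.05, 0.95), seed=seed + 91 + i)
        parts.append(s)
        phases += ["S"] * n_s_per_clone
    matrix = concat_populations(*parts)
    return matrix, pd.Series(phases, index=list(matrix.cells)), rt


def imputation_matrix(seed: int, n_a: int = 1200, n_b: int = 800,
                      noise: float = 0.05):
    """Two-clone ~2000 x 1288 matrix: diploid vs aneuploid differing by
    eight whole-chromosome copy numbers."""
    bins = make_bins(GENOME_8x16, BIN_SIZE)
    clones = [
        CloneSpec("A", {}, n_a, noise),
        CloneSpec("B", {f"chr{i}": 3 for i in range(1, 9)}, n_b, noise),
    ]
    matrix, truth = make_g1_population(clones, bins, seed=seed)
    return matrix, truth


def mixture_cohort(seed: int, scale: float = 1.0, noise: float = 0.05):
    """Two karyotype-distinct populations, each with ~25% replicating cells.

    Population A is near-diploid (~1450 cells), population B hyperdiploid
    with eight whole-chromosome differences (~750 cells).  ``scale``
    shrinks every cell count proportionally.  Returns (matrix, truth).
    """
    bins = make_bins(GENOME_10x10, BIN_SIZE)
    rt = shared_rt(len(bins), seed)

    def n(x: int) -> int:
        return max(int(round(x * scale)), 5)

    clone_a = CloneSpec("A", {"chr10": 3}, n(1090), noise)  # near-diploid
    # hyperdiploid (mean ploidy 2.2) with eight whole-chromosome differences
    karyotype_b = {f"chr{i}": 3 for i in (1, 2, 3, 4, 5)}
    karyotype_b.update({f"chr{i}": 1 for i in (6, 7, 8)})
    clone_b = CloneSpec("B", karyotype_b, n(560), noise)
    g1, g1_truth = make_g1_population([clone_a, clone_b], bins, seed=seed + 1)
    s_a, _ = make_s_population(clone_a, rt, bins, n(360), (0.05, 0.95), seed=seed + 2)
    s_b, _ = make_s_population(clone_b, rt, bins, n(190), (0.05, 0.95), seed=seed + 3)
    matrix = concat_populations(g1, s_a, s_b)
    truth = pd.DataFrame({
        "cell_id": matrix.cells,
        "population": (list(g1_truth)
                       + ["A"] * s_a.n_cells + ["B"] * s_b.n_cells),
        "phase": ["G1"] * g1.n_cells + ["S"] * (s_a.n_cells + s_b.n_cells),
    })
    return matrix, truth


def minor_clone_sample(minor_size: int, seed: int, noise: float = 0.02):
    """100 G1 cells: a dominant diploid clone plus a minor clone differing
    by ten whole-chromosome copy numbers."""
    bins = make_bins({f"chr{i}": 5_000_000 for i in range(1, 11)}, BIN_SIZE)
    clones = [
        CloneSpec("major", {}, 100 - minor_size, noise),
        CloneSpec("minor", {f"chr{i}": 3 for i in range(1, 11)}, minor_size, noise),
    ]
    return make_g1_population(clones, bins, seed=seed)


def per_population_accuracy(truth: pd.DataFrame, labels: np.ndarray,
                            cells: np.ndarray) -> dict[str, float]:
    """Fraction of each population's cells carrying its majority label."""
    table = truth.set_index("cell_id").join(
        pd.Series(labels, index=cells, name="label"))
    result = {}
    for pop, group in table.groupby("population"):
        majority = group["label"].value_counts().idxmax()
        result[str(pop)] = float((group["label"] == majority).mean())
    return result
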