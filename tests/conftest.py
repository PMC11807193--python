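import numpy as np
import pandas as pd
import pytest

from mnm.core import BinIndex, CopyNumberMatrix, make_bins
from mnm.synthetic import (
    CloneSpec,
    RTSpec,
    concat_populations,
    make_g1_population,
    make_s_population,
)


@pytest.fixture(scope="session")
def small_bins():
    """5 chromosomes x 2 Mb in 100 kb windows -> 100 bins."""
    return make_bins({f"chr{i}": 2_000_000 for i in range(1, 6)}, 100_000)


@pytest.fixture(scope="session")
def medium_bins():
    """5 chromosomes x 5 Mb in 100 kb windows -> 250 bins."""
    return make_bins({f"chr{i}": 5_000_000 for i in range(1, 6)}, 100_000)


@pytest.fixture()
def tiny_matrix():
    bins = BinIndex(["chr1"] * 3, [0, 100_000, 200_000], [100_000, 200_000, 300_000])
    values = np.array([[2.0, 3.0, np.nan], [2.0, 2.0, 2.0], [3.0, 3.0, 4.0]])
    return CopyNumberMatrix(np.array(["A", "B", "C"], dtype=object), bins, values)


@pytest.fixture(scope="session")
def two_clone_cohort(medium_bins):
    """Two karyotype-distinct clones with S cells; returns (matrix, truth)."""
    bins = medium_bins
    clone_a = CloneSpec("A", {}, n_cells=120, noise_rate=0.02)
    # triploid with gains: patterned, so S-phase cells remain attributable
    clone_b = CloneSpec(
        "B", {"chr1": 4, "chr2": 4, "chr3": 3, "chr4": 3, "chr5": 3},
        n_cells=80, noise_rate=0.02)
    g1, g1_truth = make_g1_population([clone_a, clone_b], bins, seed=5)
    rt = RTSpec.random(len(bins), 11)
    s_a, _ = make_s_population(clone_a, rt, bins, 40, (0.05, 0.95), seed=6)
    s_b, _ = make_s_population(clone_b, rt, bins, 25, (0.05, 0.95), seed=7)
    matrix = concat_populations(g1, s_a, s_b)
    truth = pd.DataFrame({
        "cell_id": matrix.cells,
        "clone": list(g1_truth) + ["A"] * 40 + ["B"] * 25,
        "phase": ["G1"] * 200 + ["S"] * 65,
    })
    return matrix, truth
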