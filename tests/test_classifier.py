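import numpy as np
import pandas as pd
import pytest

from mnm.classifier import (
    ModelBundle,
    TrainingSet,
    audit_discordance,
    augment_training,
    build_training_set,
    predict_states,
    train_classifier,
)
from mnm.core import BinIndex, CopyNumberMatrix
from mnm.synthetic import (
    CloneSpec,
    RTSpec,
    concat_populations,
    make_g1_population,
    make_s_population,
)


def toy_cohort(bins, n_per_class=100, noise=0.02, progress=(0.5, 0.5), seed=1,
               rt_seed=None):
    # rt_seed pins the replication programme: cohorts meant to be classified
    # by the same model must share it (RT is a property of the genome, not
    # of the cohort)
    clone = CloneSpec("A", {}, n_cells=n_per_class, noise_rate=noise)
    g1, _ = make_g1_population([clone], bins, seed=seed)
    rt = RTSpec.random(len(bins), seed + 1 if rt_seed is None else rt_seed)
    s, _ = make_s_population(clone, rt, bins, n_per_class, progress, seed=seed + 2)
    matrix = concat_populations(g1, s)
    phases = pd.Series(["G1"] * n_per_class + ["S"] * n_per_class,
                       index=list(matrix.cells))
    return matrix, phases


@pytest.fixture(scope="module")
def toy_training(medium_bins):
    matrix, phases = toy_cohort(medium_bins, n_per_class=100)
    return build_training_set(matrix, phases)


class TestTrainingSet:
    def test_drops_incomplete_bins_and_sex_chromosomes(self):
        bins = BinIndex.from_records(
            [("chr1", 0, 100), ("chr1", 100, 200), ("chrX", 0, 100)])
        values = np.array([[2.0, np.nan, 2.0], [2.0, 3.0, 1.0]])
        m = CopyNumberMatrix(np.array(["a", "b"], dtype=object), bins, values)
        ts = build_training_set(m, {"a": "G1", "b": "S"})
        assert ts.region_labels == ["chr1:0-100"]
        assert ts.features.shape == (2, 1)
        np.testing.assert_array_equal(ts.labels, [0, 1])

    def test_rejects_nan_features(self):
        with pytest.raises(ValueError, match="missing"):
            TrainingSet(np.array([[np.nan]]), np.array([0]), ["chr1:0-1"])


class TestAugmentation:
    def test_cell_count_150_from_100(self, toy_training):
        out = augment_training(toy_training, seed=0)
        assert out.features.shape[0] == 300  # 200 + 0.5*200
        ts100 = TrainingSet(toy_training.features[:100], toy_training.labels[:100],
                            toy_training.region_labels)
        assert augment_training(ts100, seed=0).features.shape[0] == 150

    def test_exact_altered_bin_count(self, toy_training):
        n_bins = toy_training.features.shape[1]
        out = augment_training(toy_training, dup_fraction=0.05,
                               noise_span=(0.05, 0.05), seed=1)
        originals = {tuple(row) for row in toy_training.features}
        n_orig = toy_training.features.shape[0]
        for dup in out.features[n_orig:]:
            diffs = [int((dup != o).sum()) for o in toy_training.features]
            assert min(diffs) == round(0.05 * n_bins)

    def test_zero_span_duplicates_identical(self, toy_training):
        out = augment_training(toy_training, noise_span=(0.0, 0.0), seed=2)
        n_orig = toy_training.features.shape[0]
        originals = {tuple(row) for row in toy_training.features}
        assert all(tuple(row) in originals for row in out.features[n_orig:])

    def test_invalid_span(self, toy_training):
        with pytest.raises(ValueError, match="noise_span"):
            augment_training(toy_training, noise_span=(0.5, 1.5))


class TestTraining:
    def test_separable_toy_perfect_accuracy(self, toy_training):
        bundle, acc = train_classifier(toy_training, seed=7, max_epochs=150)
        assert acc == 1.0
        assert bundle.layer_sizes[1:] == [64, 32, 16, 1]

    def test_label_shuffle_near_chance(self, medium_bins, toy_training):
        rng = np.random.default_rng(0)
        shuffled = TrainingSet(toy_training.features,
                               rng.permutation(toy_training.labels),
                               toy_training.region_labels)
        _, acc = train_classifier(shuffled, seed=7, max_epochs=60)
        assert 0.25 < acc < 0.75

    def test_deterministic_for_fixed_seed(self, toy_training):
        b1, a1 = train_classifier(toy_training, seed=3, max_epochs=40)
        b2, a2 = train_classifier(toy_training, seed=3, max_epochs=40)
        assert a1 == a2
        for w1, w2 in zip(b1.weights, b2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_single_class_rejected(self, toy_training):
        ones = TrainingSet(toy_training.features,
                           np.ones_like(toy_training.labels),
                           toy_training.region_labels)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ones)

    def test_class_balance_robustness(self, medium_bins):
        accs = {}
        for name, (n_g1, n_s) in {"1:2": (60, 120), "2:1": (120, 60)}.items():
            clone = CloneSpec("A", {}, n_cells=n_g1, noise_rate=0.02)
            g1, _ = make_g1_population([clone], medium_bins, seed=11)
            rt = RTSpec.random(len(medium_bins), 12)
            s, _ = make_s_population(clone, rt, medium_bins, n_s, (0.1, 0.9), seed=13)
            matrix = concat_populations(g1, s)
            phases = pd.Series(["G1"] * n_g1 + ["S"] * n_s, index=list(matrix.cells))
            _, acc = train_classifier(build_training_set(matrix, phases),
                                      seed=5, max_epochs=120)
            accs[name] = acc
        assert abs(accs["1:2"] - accs["2:1"]) <= 0.02


class TestModelBundle:
    def test_layer_width_invariant(self):
        with pytest.raises(ValueError, match="layer widths"):
            ModelBundle([10, 8, 1], [np.zeros((10, 8)), np.zeros((8, 1))],
                        [np.zeros(8), np.zeros(1)], ["chr1:0-1"])

    def test_empty_region_list(self):
        sizes = [4, 64, 32, 16, 1]
        ws = [np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
        bs = [np.zeros(b) for b in sizes[1:]]
        with pytest.raises(ValueError, match="region list"):
            ModelBundle(sizes, ws, bs, [])

    def test_save_load_roundtrip(self, toy_training, tmp_path):
        bundle, _ = train_classifier(toy_training, seed=2, max_epochs=20)
        path = tmp_path / "model.mnm"
        bundle.save(path)
        again = ModelBundle.load(path)
        for w1, w2 in zip(bundle.weights, again.weights):
            np.testing.assert_allclose(w1, w2)
        assert again.region_labels == bundle.region_labels


@pytest.fixture(scope="module")
def trained(medium_bins):
    matrix, phases = toy_cohort(medium_bins, n_per_class=100,
                                progress=(0.3, 0.7), seed=21)
    bundle, _ = train_classifier(build_training_set(matrix, phases),
                                 seed=9, max_epochs=120)
    return bundle


class TestPrediction:
    def test_probabilities_and_labels(self, trained, medium_bins):
        matrix, phases = toy_cohort(medium_bins, n_per_class=30,
                                    progress=(0.3, 0.7), seed=31, rt_seed=22)
        calls = predict_states(trained, matrix)
        assert len(calls) == matrix.n_cells  # no cell dropped
        assert calls["probability"].between(0, 1).all()
        assert ((calls["probability"] >= 0.5) == (calls["phase"] == "S")).all()
        agree = (calls.set_index("cell_id")["phase"] == phases).mean()
        assert agree > 0.95

    def test_absent_bin_interpolated_midpoint(self, trained, medium_bins):
        from mnm.classifier import _align_features

        matrix, _ = toy_cohort(medium_bins, n_per_class=2, seed=41)
        keep = np.ones(matrix.n_bins, dtype=bool)
        drop = 5  # interior bin of chr1
        keep[drop] = False
        reduced = matrix.select_bins(keep)
        reduced.values[0, 4] = 2.0
        reduced.values[0, 5] = 4.0  # flanks of the dropped bin
        aligned = _align_features(reduced, trained.region_labels)
        assert aligned[0, drop] == pytest.approx(3.0)

    def test_chromosome_end_one_sided_extension(self, trained, medium_bins):
        from mnm.classifier import _align_features

        matrix, _ = toy_cohort(medium_bins, n_per_class=2, seed=42)
        keep = np.ones(matrix.n_bins, dtype=bool)
        keep[0] = False  # first bin of chr1
        reduced = matrix.select_bins(keep)
        reduced.values[0, 0] = 4.0  # nearest observed value on chr1
        aligned = _align_features(reduced, trained.region_labels)
        assert aligned[0, 0] == pytest.approx(4.0)

    def test_no_overlap_rejected(self, trained):
        bins = BinIndex.from_records([("chr9", 0, 100_000)])
        m = CopyNumberMatrix(np.array(["x"], dtype=object), bins, np.array([[2.0]]))
        with pytest.raises(ValueError, match="no overlap"):
            predict_states(trained, m)

    def test_doubled_cell_scores_higher(self, medium_bins):
        # training includes end-of-S (fully doubled) cells so a constant-4
        # profile is in-distribution for the replicating class
        clone = CloneSpec("A", {}, n_cells=150, noise_rate=0.02)
        g1, _ = make_g1_population([clone], medium_bins, seed=51)
        rt = RTSpec.random(len(medium_bins), 52)
        s_mid, _ = make_s_population(clone, rt, medium_bins, 120, (0.1, 0.95), seed=53)
        s_end, _ = make_s_population(clone, rt, medium_bins, 30, (1.0, 1.0), seed=54)
        s_end.cells = np.array([c + "_end" for c in s_end.cells], dtype=object)
        matrix = concat_populations(g1, s_mid, s_end)
        phases = pd.Series(["G1"] * 150 + ["S"] * 150, index=list(matrix.cells))
        bundle, _ = train_classifier(build_training_set(matrix, phases),
                                     seed=6, max_epochs=150)
        n = len(medium_bins)
        twins = CopyNumberMatrix(
            np.array(["g1_twin", "doubled"], dtype=object), medium_bins,
            np.vstack([np.full(n, 2.0), np.full(n, 4.0)]))
        calls = predict_states(bundle, twins)
        assert calls["probability"].iloc[1] > calls["probability"].iloc[0]


def test_audit_discordance():
    calls = pd.DataFrame({"cell_id": list("abcd"),
                          "probability": [0.9, 0.1, 0.8, 0.2],
                          "phase": ["S", "G1", "S", "G1"]})
    external = {"a": "S", "b": "S", "c": "G1", "d": "G1"}
    assert audit_discordance(calls, external) == 50.0
    with pytest.raises(ValueError, match="share"):
        audit_discordance(calls, {"zz": "S"})
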