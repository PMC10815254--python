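"""Cross-validation bookkeeping, stratification, permutation null, seed scan."""

import numpy as np
import pytest

import dlrpmds as d
from dlrpmds.classifier import ClassifierConfig
from dlrpmds.datatypes import ValidationError


def latent_set(X, y, ids=None):
    if ids is None:
        ids = [f"v{i}" for i in range(len(y))]
    return d.LabeledLatentSet(latents=X, labels=y, variant_ids=np.array(ids))


FAST = ClassifierConfig(width=16, epochs=5, seed=0)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 4))
    y = np.array([0] * 100 + [1] * 100)
    X[y == 1, 0] += 8.0
    return latent_set(X, y)


class TestCrossValidate:
    def test_four_folds_five_repeats_trains_twenty_models(self, separable):
        report = d.cross_validate(separable, folds=4, repeats=5, seed=0,
                                  classifier_config=FAST)
        assert report.n_models == 20
        assert set(report.results["repeat"]) == set(range(5))
        assert set(report.results["fold"]) == set(range(4))

    def test_every_sample_in_exactly_one_test_fold_per_repeat(self, separable):
        report = d.cross_validate(separable, folds=4, repeats=3, seed=1,
                                  classifier_config=FAST)
        for fold_of in report.fold_assignments:
            assert np.all(fold_of >= 0)  # every sample assigned
            counts = np.bincount(fold_of, minlength=4)
            assert counts.sum() == separable.n

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(90, 3))
        y = np.array([0] * 60 + [1] * 30)
        X[y == 1] += 6.0
        report = d.cross_validate(latent_set(X, y), folds=4, repeats=2, seed=0,
                                  classifier_config=FAST)
        for fold_of in report.fold_assignments:
            for f in range(4):
                in_fold = fold_of == f
                n1 = int(np.sum(y[in_fold]))
                expected = in_fold.sum() * 30 / 90
                assert abs(n1 - expected) <= 1

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(1000, 4))
        X[:500, 0] += 8.0
        y = rng.permutation(np.array([0] * 500 + [1] * 500))  # labels shuffled
        report = d.cross_validate(latent_set(X, y), folds=4, repeats=2, seed=0,
                                  classifier_config=FAST)
        assert 0.4 <= report.mean_test_auc <= 0.6

    def test_reproducible_under_fixed_seed(self, separable):
        r1 = d.cross_validate(separable, folds=4, repeats=2, seed=7,
                              classifier_config=FAST)
        r2 = d.cross_validate(separable, folds=4, repeats=2, seed=7,
                              classifier_config=FAST)
        assert r1.results.equals(r2.results)

    def test_class_smaller_than_fold_count_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([1, 1, 1] + [0] * 7)
        with pytest.raises(ValidationError):
            d.cross_validate(latent_set(X, y), folds=4, repeats=1)

    def test_grouped_mode_keeps_variants_intact(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        y = np.repeat([0, 1], 40)
        X[y == 1] += 6.0
        groups = np.repeat(np.arange(16), 5)  # 16 variants x 5 frames
        report = d.cross_validate(latent_set(X, y), folds=4, repeats=1, seed=0,
                                  classifier_config=FAST, groups=groups)
        fold_of = report.fold_assignments[0]
        for g in range(16):
            assert len(set(fold_of[groups == g])) == 1


class TestScanSeeds:
    def test_single_seed_is_chosen(self):
        res = d.scan_seeds(seeds=[42], evaluate=lambda s: (5, 0.9))
        assert res.chosen_seed == 42

    def test_argmin_of_deleterious_calls(self):
        counts = {0: 7, 100: 3, 200: 9}
        res = d.scan_seeds(seeds=list(counts),
                           evaluate=lambda s: (counts[s], 1.0))
        assert res.chosen_seed == 100

    def test_ties_broken_by_smallest_seed(self):
        res = d.scan_seeds(seeds=[300, 100, 200],
                           evaluate=lambda s: (3, 1.0))
        assert res.chosen_seed == 100

    def test_zero_is_a_valid_chosen_seed(self):
        res = d.scan_seeds(seeds=[0, 100], evaluate=lambda s: (s // 100, 1.0))
        assert res.chosen_seed == 0

    def test_failed_seeds_excluded_with_warning(self):
        def evaluate(s):
            if s == 0:
                raise RuntimeError("diverged")
            return (1, 0.8)

        with pytest.warns(UserWarning, match="seed 0 failed"):
            res = d.scan_seeds(seeds=[0, 100], evaluate=evaluate)
        assert res.chosen_seed == 100
        assert res.table["failed"].tolist() == [True, False]

    def test_default_grid_matches_protocol(self):
        from dlrpmds.model_selection import DEFAULT_SEED_GRID

        assert DEFAULT_SEED_GRID[0] == 0
        assert DEFAULT_SEED_GRID[-1] == 10000
        assert len(DEFAULT_SEED_GRID) == 101

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValidationError):
            d.scan_seeds(seeds=[], evaluate=lambda s: (0, 0.5))

    def test_end_to_end_scan_on_tiny_pipeline(self, small_two_class):
        unknown = d.simulate_trajectory(
            d.make_class_spec("unknown", n_residues=10, n_variants=1,
                              n_frames_per_variant=30, seed=11), 0)
        cfg = d.PipelineConfig(
            autoencoder=d.AEConfig(hidden_widths=[16], latent_dim=3, epochs=3),
            classifier=ClassifierConfig(width=16, epochs=3),
            run_cv=False,
        )
        res = d.scan_seeds(small_two_class, [unknown], seeds=[0, 1],
                           pipeline_config=cfg)
        assert res.chosen_seed in (0, 1)
        assert not res.table["failed"].any()
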