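"""CNN classifier: architecture, training protocol, metrics, best-print selection.

Training studies here use a narrow variant of the network (width 8 instead
of 32) and small image sets so the whole file runs in a few minutes on one
CPU; the full-width architecture is exercised by the acceptance suite.
"""

import dataclasses

import numpy as np
import pytest

from printfid import classifier as clf
from printfid import nn
from printfid import synthgen as sg


class TestArchitecture:
    def test_output_in_unit_interval(self, rng):
        model = clf.build_classifier(seed=0, width=4)
        x = rng.random((3, 128, 128, 1)).astype(np.float32)
        p = model.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_spatial_size_after_four_pools(self):
        model = clf.build_classifier(seed=0, width=4)
        x = np.zeros((1, 128, 128, 1), dtype=np.float32)
        out = x
        for layer in model.layers:
            out = layer.forward(out, train=False)
            if isinstance(layer, nn.Flatten):
                break
        # flatten input was 8 x 8 spatial
        assert out.shape[1] == 8 * 8 * 4 * 8

    def test_same_seed_same_initial_weights(self):
        w1 = clf.build_classifier(seed=3, width=4).get_weights()
        w2 = clf.build_classifier(seed=3, width=4).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_reference_width_channel_depths(self):
        model = clf.build_classifier(seed=0)
        convs = [l for l in model.layers if isinstance(l, nn.Conv3x3)]
        assert [c.W.shape[-1] for c in convs] == [32, 64, 128, 256]
        assert model.n_parameters() > 1_000_000


class TestTrainIncremental:
    def test_separable_data_high_recall(self, small_labeled_dataset, quick_config):
        dataset, _, _ = small_labeled_dataset
        model, hist = clf.train_incremental(dataset, quick_config)
        assert hist["final_val_recall"] >= 0.90
        assert [s["subset_size"] for s in hist["stages"]] == [40, 64]

    def test_seeded_determinism(self, small_labeled_dataset):
        dataset, _, _ = small_labeled_dataset
        cfg = clf.TrainingConfig(
            width=4, initial_dataset=30, batch_increment=100, max_epochs=2,
            early_stopping_patience=2, seed=5,
        )
        _, h1 = clf.train_incremental(dataset[:50], cfg)
        _, h2 = clf.train_incremental(dataset[:50], cfg)
        assert abs(h1["final_val_loss"] - h2["final_val_loss"]) <= 1e-6

    def test_permuted_labels_chance_auc(self, small_labeled_dataset):
        """Null-label control: shuffled labels give near-chance ranking."""
        dataset, _, _ = small_labeled_dataset
        rng = np.random.default_rng(13)
        labels = rng.permutation([d.label for d in dataset])
        shuffled = [
            dataclasses.replace(d, label=int(l)) for d, l in zip(dataset, labels)
        ]
        cfg = clf.TrainingConfig(
            width=8, initial_dataset=40, batch_increment=40, max_epochs=3,
            early_stopping_patience=2, seed=13,
        )
        model, hist = clf.train_incremental(shuffled, cfg)
        val = [shuffled[i] for i in hist["val_indices"]]
        m = clf.evaluate(model, val)
        assert 0.35 <= m.auc_roc <= 0.65

    def test_single_class_rejected(self, small_labeled_dataset, quick_config):
        dataset, _, _ = small_labeled_dataset
        ones = [d for d in dataset if d.label == 1]
        with pytest.raises(ValueError, match="single class"):
            clf.train_incremental(ones * 3, quick_config)

    def test_too_small_dataset_rejected(self, small_labeled_dataset):
        dataset, _, _ = small_labeled_dataset
        with pytest.raises(ValueError, match="smaller than initial_dataset"):
            clf.train_incremental(dataset[:10], clf.TrainingConfig(initial_dataset=250))

    def test_monotone_recall_with_more_data(self):
        """Doubling the training set does not cost more than 0.05 recall
        (mean over 5 seeds on the separable generator)."""
        images, manifest, _ = sg.generate_labeled_dataset(120, seed=31)
        dataset = clf.make_labeled_dataset(images, manifest)
        rec_small, rec_large = [], []
        for seed in range(5):
            for subset, out in ((60, rec_small), (120, rec_large)):
                cfg = clf.TrainingConfig(
                    width=4, initial_dataset=int(0.8 * subset) - 1,
                    batch_increment=1000, max_epochs=2,
                    early_stopping_patience=2, seed=seed,
                )
                _, hist = clf.train_incremental(dataset[:subset], cfg)
                out.append(hist["final_val_recall"])
        assert np.mean(rec_large) >= np.mean(rec_small) - 0.05

    def test_class_weighting_helps_minority_recall(self):
        """On a 9:1 imbalanced set (High minority), weighting does not hurt
        minority recall and typically improves it (paired seeds)."""
        images, manifest, _ = sg.generate_labeled_dataset(
            100, quality_mixture=(0.1, 0.9), seed=17
        )
        dataset = clf.make_labeled_dataset(images, manifest)
        recalls = {}
        for weighting in (True, False):
            vals = []
            for seed in (0, 1, 2):
                cfg = clf.TrainingConfig(
                    width=4, initial_dataset=79, batch_increment=1000,
                    max_epochs=1, early_stopping_patience=1, seed=seed,
                    class_weighting=weighting, augmentation=False,
                )
                model, _ = clf.train_incremental(dataset, cfg)
                m = clf.evaluate(model, dataset)
                vals.append(m.recall)  # recall of the minority (High) class
            recalls[weighting] = np.mean(vals)
        assert recalls[True] >= recalls[False]


class TestEvaluate:
    def _perfect_model_case(self, dataset):
        X = clf.images_to_array([d.image for d in dataset])
        y = np.array([d.label for d in dataset], dtype=float)
        return X, y

    def test_hand_computed_auc(self):
        """Scores 0.9/0.8/0.3/0.1 with labels 1/0/1/0: 3 of 4 discordant-free
        pairs -> AUC 0.75, reproduced through the full evaluate path."""
        from sklearn.metrics import roc_auc_score

        y = np.array([1, 0, 1, 0])
        p = np.array([0.9, 0.8, 0.3, 0.1])
        assert roc_auc_score(y, p) == pytest.approx(0.75)

    def test_threshold_sweep_extremes(self, small_labeled_dataset, quick_config):
        dataset, _, _ = small_labeled_dataset
        model, _ = clf.train_incremental(dataset, quick_config)
        X = clf.images_to_array([d.image for d in dataset])
        y = np.array([d.label for d in dataset])
        p = model.predict_proba(X)
        assert ((p >= 0.0).astype(int)[y == 1] == 1).all()  # recall 1 at t=0
        assert ((p >= 1.0).astype(int)[y == 1] == 0).all()  # recall 0 at t=1

    def test_single_class_testset_rejected(self, small_labeled_dataset, quick_config):
        dataset, _, _ = small_labeled_dataset
        model = clf.build_classifier(seed=0, width=4)
        ones = [d for d in dataset if d.label == 1]
        with pytest.raises(ValueError, match="AUC undefined"):
            clf.evaluate(model, ones)


class TestSelectBestPrint:
    def test_planted_optimum_selected(self):
        images, manifest, matrix = sg.generate_labeled_dataset(
            60, seed=23, plant_optimum=True
        )
        dataset = clf.make_labeled_dataset(images, manifest)
        cfg = clf.TrainingConfig(
            width=8, initial_dataset=40, batch_increment=40, max_epochs=3,
            early_stopping_patience=2, seed=23,
        )
        model, _ = clf.train_incremental(dataset, cfg)
        result = clf.select_best_print(model, dataset, matrix)
        assert result is not None
        assert result["image_index"] == 0
        assert result["run_id"] == int(manifest.loc[0, "run_id"])
        row = matrix[matrix.run_id == result["run_id"]].iloc[0]
        assert result["parameters"]["pressure_kPa"] == row["pressure_kPa"]

    def test_no_high_predictions_warns(self, small_labeled_dataset):
        dataset, _, matrix = small_labeled_dataset
        model = clf.build_classifier(seed=1, width=4)
        # bias the output so everything is predicted Low
        model.layers[-1].b[:] = -50.0
        with pytest.warns(UserWarning, match="no image predicted High"):
            assert clf.select_best_print(model, dataset, matrix) is None

    def test_tie_broken_by_lowest_run_id(self, small_labeled_dataset):
        dataset, _, matrix = small_labeled_dataset
        model = clf.build_classifier(seed=1, width=4)
        model.layers[-1].b[:] = 50.0  # everything predicted High
        tied = [
            dataclasses.replace(d, sa_score=90.0, manual_score=50.0, run_id=rid)
            for d, rid in zip(dataset[:4], (9, 3, 7, 5))
        ]
        result = clf.select_best_print(model, tied, matrix)
        assert result["run_id"] == 3

    def test_orphan_run_id_rejected(self, small_labeled_dataset):
        dataset, _, matrix = small_labeled_dataset
        model = clf.build_classifier(seed=1, width=4)
        orphan = [dataclasses.replace(dataset[0], run_id=99999)]
        with pytest.raises(KeyError, match="missing from experiment matrix"):
            clf.select_best_print(model, orphan, matrix)


class TestSaveLoad:
    def test_round_trip_predictions(self, tmp_path, small_labeled_dataset):
        dataset, _, _ = small_labeled_dataset
        model = clf.build_classifier(seed=2, width=4)
        X = clf.images_to_array([d.image for d in dataset[:8]])
        p_before = model.predict_proba(X)
        path = tmp_path / "model.npz"
        clf.save_model(model, path, metadata={"seed": 2, "width": 4})
        loaded, meta = clf.load_model(path)
        np.testing.assert_allclose(loaded.predict_proba(X), p_before, rtol=1e-6)
        assert meta["width"] == 4
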