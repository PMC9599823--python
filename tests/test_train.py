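"""Splitting, the joint training loop, leakage guards, and experiment records."""

import numpy as np
import pytest

import gcndecode as g
from gcndecode.train import run_trial

from conftest import TINY_GRID


def _small_experiment_parts(tiny_dataset, tiny_stream_config):
    gcn_cfg = g.GCNConfig(n_blocks=2, n_classes=tiny_dataset.config.n_classes)
    return tiny_stream_config, gcn_cfg


@pytest.fixture(scope="module")
def three_subject_dataset():
    cfg = g.GeneratorConfig(n_subjects=3, scans_per_class_per_subject=3,
                            n_classes=4, effect_size=2.0, seed=21,
                            grid=TINY_GRID)
    return g.generate_dataset(cfg)


class TestSplits:
    def test_five_subject_rotation(self):
        splits = g.make_splits([0, 1, 2, 3, 4])
        assert len(splits) == 5
        for s in splits:
            roles = set(s.train_subjects) | {s.val_subject, s.test_subject}
            assert roles == {0, 1, 2, 3, 4}
            assert len(s.train_subjects) == 3
        assert len({s.test_subject for s in splits}) == 5

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            g.make_splits([0, 1])

    def test_under_five_warns(self):
        with pytest.warns(UserWarning, match="subjects"):
            g.make_splits([0, 1, 2])

    def test_overlapping_roles_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            g.SplitScheme(trial=1, train_subjects=(0, 1), val_subject=1,
                          test_subject=2)


class TestTrainingLoop:
    def test_loss_decreases_on_learnable_data(self, three_subject_dataset,
                                              tiny_stream_config):
        stream_cfg, gcn_cfg = _small_experiment_parts(three_subject_dataset,
                                                      tiny_stream_config)
        tr = g.TrainConfig(epochs=5, seed=3)
        split = g.make_splits([0, 1, 2], n_trials=1)[0]
        rec = run_trial(three_subject_dataset, split, stream_cfg, gcn_cfg, tr)
        assert rec["history"][-1]["train_loss"] < rec["history"][0]["train_loss"]

    def test_zero_learning_rate_freezes_parameters(self, three_subject_dataset,
                                                   tiny_stream_config):
        from gcndecode.graph import (build_adjacency, normalize_adjacency,
                                     training_roi_signals)
        from gcndecode.train import build_model, train

        ds = three_subject_dataset
        scans = g.normalize_by_subject(ds.scans)
        trn = [s for s in scans if s.subject in (0, 1)]
        val = [s for s in scans if s.subject == 2]
        a_hat = normalize_adjacency(build_adjacency(
            training_roi_signals(trn, ds.template)))
        stream_cfg, gcn_cfg = _small_experiment_parts(ds, tiny_stream_config)
        model = build_model(ds.template, a_hat, stream_cfg, gcn_cfg, seed=0)
        before = [p.value.copy() for p in model.params()]
        train(model, trn, val, g.TrainConfig(epochs=1, learning_rate=0.0,
                                             weight_decay=0.0, seed=0))
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_fixed_seed_reproduces_loss_history(self, three_subject_dataset,
                                                tiny_stream_config):
        stream_cfg, gcn_cfg = _small_experiment_parts(three_subject_dataset,
                                                      tiny_stream_config)
        tr = g.TrainConfig(epochs=3, seed=8)
        split = g.make_splits([0, 1, 2], n_trials=1)[0]
        a = run_trial(three_subject_dataset, split, stream_cfg, gcn_cfg, tr)
        b = run_trial(three_subject_dataset, split, stream_cfg, gcn_cfg, tr)
        assert a["history"] == b["history"]
        assert a["metrics"] == b["metrics"]

    def test_empty_split_role_raises(self, three_subject_dataset,
                                     tiny_stream_config):
        from gcndecode.train import SplitScheme

        stream_cfg, gcn_cfg = _small_experiment_parts(three_subject_dataset,
                                                      tiny_stream_config)
        bad = SplitScheme(trial=1, train_subjects=(0, 1), val_subject=2,
                          test_subject=9)  # subject 9 has no scans
        with pytest.raises(ValueError, match="empty"):
            run_trial(three_subject_dataset, bad, stream_cfg, gcn_cfg,
                      g.TrainConfig(epochs=1, seed=0))


class TestNoLeakage:
    def test_adjacency_uses_training_subjects_only(self, three_subject_dataset):
        ds = three_subject_dataset
        scans = g.normalize_by_subject(ds.scans)
        trn = [s for s in scans if s.subject in (0, 1)]
        sig_train_only = g.training_roi_signals(scans, ds.template,
                                                train_subjects={0, 1})
        np.testing.assert_allclose(
            sig_train_only, g.training_roi_signals(trn, ds.template)
        )
        # including the held-out subject demonstrably changes the signals
        sig_all = g.training_roi_signals(scans, ds.template)
        assert sig_all.shape != sig_train_only.shape

    def test_trial_adjacency_matches_train_only_recomputation(
        self, three_subject_dataset, tiny_stream_config
    ):
        from gcndecode.graph import build_adjacency

        ds = three_subject_dataset
        stream_cfg, gcn_cfg = _small_experiment_parts(ds, tiny_stream_config)
        split = g.make_splits([0, 1, 2], n_trials=1)[0]
        rec = run_trial(ds, split, stream_cfg, gcn_cfg,
                        g.TrainConfig(epochs=1, seed=0))
        scans = g.normalize_by_subject(ds.scans)
        trn = [s for s in scans if s.subject in split.train_subjects]
        expected = build_adjacency(
            g.training_roi_signals(trn, ds.template)).A
        np.testing.assert_allclose(np.array(rec["adjacency"]), expected)

    def test_subject_normalization_is_local(self, three_subject_dataset):
        ds = three_subject_dataset
        all_norm = g.normalize_by_subject(ds.scans)
        only01 = g.normalize_by_subject(
            [s for s in ds.scans if s.subject in (0, 1)]
        )
        # subject 0's normalized data is identical whether subject 2 exists
        a = [s for s in all_norm if s.subject == 0]
        b = [s for s in only01 if s.subject == 0]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)


class TestCheckpoint:
    def test_round_trip_restores_predictions(self, three_subject_dataset,
                                             tiny_stream_config, tmp_path):
        from gcndecode.graph import (build_adjacency, normalize_adjacency,
                                     training_roi_signals)
        from gcndecode.train import (build_model, load_checkpoint,
                                     save_checkpoint, train)

        ds = three_subject_dataset
        scans = g.normalize_by_subject(ds.scans)
        trn = [s for s in scans if s.subject in (0, 1)]
        val = [s for s in scans if s.subject == 2]
        a_hat = normalize_adjacency(build_adjacency(
            training_roi_signals(trn, ds.template)))
        stream_cfg, gcn_cfg = _small_experiment_parts(ds, tiny_stream_config)
        model = build_model(ds.template, a_hat, stream_cfg, gcn_cfg, seed=4)
        train(model, trn, val, g.TrainConfig(epochs=2, seed=4))
        x = np.stack([s.data for s in val]).astype(np.float32)
        before = model.predict(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        fresh = build_model(ds.template, a_hat, stream_cfg, gcn_cfg, seed=99)
        load_checkpoint(fresh, path)
        np.testing.assert_array_equal(fresh.predict(x), before)


class TestExperimentRecord:
    def test_protocol_structure_and_round_trip(self, tmp_path,
                                               tiny_stream_config):
        cfg = g.GeneratorConfig(n_subjects=5, scans_per_class_per_subject=1,
                                n_classes=3, effect_size=2.0, seed=31,
                                grid=TINY_GRID)
        ds = g.generate_dataset(cfg)
        gcn_cfg = g.GCNConfig(n_blocks=1, n_classes=3)
        record = g.run_experiment(ds, tiny_stream_config, gcn_cfg,
                                  g.TrainConfig(epochs=1, seed=0), n_trials=5)
        assert len(record.per_trial) == 5
        tests = [t["split"]["test"] for t in record.per_trial]
        assert sorted(tests) == [0, 1, 2, 3, 4]
        for t in record.per_trial:
            roles = set(t["split"]["train"]) | {t["split"]["val"], t["split"]["test"]}
            assert len(roles) == 5
        path = tmp_path / "exp.json"
        path.write_text(record.to_json())
        back = g.ExperimentRecord.from_json(path.read_text())
        assert back.per_trial == record.per_trial
        assert back.mean_total_accuracy == record.mean_total_accuracy
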