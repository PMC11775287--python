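"""Model assembly, prediction head, splits, and training protocols."""

import numpy as np
import pytest

from dualdta.model import DTAModel, ModelConfig, prepare_pairs
from dualdta.nn import Tensor
from dualdta.training import (
    SplitSpec,
    TrainConfig,
    evaluate,
    make_splits,
    train_joint,
    train_model,
    train_warmup,
)


class TestPredictAffinity:
    def test_zero_weights_return_bias(self, tiny_model):
        head = tiny_model.head
        for i in range(head.n_layers):
            getattr(head, f"lin{i}").weight.data[:] = 0.0
            getattr(head, f"lin{i}").bias.data[:] = 0.0
        head.lin1.bias.data[:] = 2.5
        out_seq = Tensor(np.random.default_rng(0).normal(size=(3, tiny_model.seq.out_dim)))
        out_str = Tensor(np.random.default_rng(1).normal(size=(3, 16)))
        pred = tiny_model.predict_affinity(out_seq, out_str)
        np.testing.assert_allclose(pred.data, 2.5)

    def test_deterministic(self, tiny_model, rng):
        out_seq = Tensor(rng.normal(size=(2, tiny_model.seq.out_dim)))
        out_str = Tensor(rng.normal(size=(2, 16)))
        a = tiny_model.predict_affinity(out_seq, out_str).data
        b = tiny_model.predict_affinity(out_seq, out_str).data
        np.testing.assert_array_equal(a, b)

    def test_concat_order_out_str_first(self, tiny_model, rng):
        """Regression pin: the head consumes concat(out_str, out_seq)."""
        out_seq = Tensor(rng.normal(size=(1, tiny_model.seq.out_dim)))
        out_str = Tensor(rng.normal(size=(1, 16)))
        got = tiny_model.predict_affinity(out_seq, out_str).data
        manual = np.concatenate([out_str.data, out_seq.data], axis=1)
        h = manual @ tiny_model.head.lin0.weight.data + tiny_model.head.lin0.bias.data
        h = np.maximum(h, 0.0)
        want = h @ tiny_model.head.lin1.weight.data + tiny_model.head.lin1.bias.data
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_dimension_mismatch_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.predict_affinity(
                Tensor(rng.normal(size=(1, 4))), Tensor(rng.normal(size=(1, 4)))
            )


class TestForward:
    def test_eval_forward_deterministic_and_padding_stable(
        self, tiny_model, tiny_pairs
    ):
        tiny_model.eval()
        batch = tiny_pairs[:6]
        a = tiny_model.predict(batch, batch_size=6)
        b = tiny_model.predict(batch, batch_size=6)
        np.testing.assert_array_equal(a, b)
        # different batch composition -> different padding, same predictions
        c = tiny_model.predict(batch, batch_size=2)
        np.testing.assert_allclose(a, c, atol=1e-8)

    def test_batch_order_stability(self, tiny_model, tiny_pairs):
        tiny_model.eval()
        batch = tiny_pairs[:8]
        base = tiny_model.predict(batch, batch_size=8)
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        permuted = tiny_model.predict([batch[i] for i in perm], batch_size=8)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-8)

    def test_save_load_roundtrip(self, tiny_model, tiny_pairs, tmp_path):
        tiny_model.eval()
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = DTAModel.load(path)
        np.testing.assert_array_equal(
            tiny_model.predict(tiny_pairs[:5]), loaded.predict(tiny_pairs[:5])
        )


ABLATIONS = [
    {"use_gem": False},
    {"use_link_attention": False},
    {"use_virtual_node": False},
    {"use_source_feature": False},
    {"seq_only": True},
    {"graph_only": True},
    {"virtual_self_loop": True},
]


@pytest.mark.parametrize("flags", ABLATIONS, ids=lambda f: next(iter(f)))
def test_ablations_train_end_to_end(flags, tiny_model_config, tiny_pairs):
    """Every component toggle must support a full train/predict cycle."""
    cfg = ModelConfig.from_dict({**tiny_model_config.to_dict(), **flags})
    model = DTAModel(cfg, seed=1)
    tc = TrainConfig(
        warmup_epochs=1, joint_epochs=2, lr=1e-3, batch_size=16, seed=0, patience=5
    )
    history = train_model(model, tiny_pairs[:32], tiny_pairs[32:40], tc)
    assert len(history["train_mse"]) >= 1
    preds = model.predict(tiny_pairs[40:48])
    assert preds.shape == (8,)
    assert np.all(np.isfinite(preds))


class TestWarmup:
    def test_zero_epochs_leave_weights_at_initialization(
        self, tiny_model, tiny_pairs
    ):
        before = {k: v.copy() for k, v in tiny_model.state_dict().items()}
        tc = TrainConfig(warmup_epochs=0, joint_epochs=1, lr=1e-3, batch_size=8, seed=0)
        train_warmup(tiny_model, tiny_pairs[:16], tc)
        after = tiny_model.state_dict()
        for k in before:
            if k.endswith("y_offset"):
                continue
            np.testing.assert_array_equal(before[k], after[k])

    def test_warmup_beats_constant_predictor_on_noise_free_data(self):
        from dualdta.synthetic import PlantedAffinityModel, gen_dataset
        from dualdta.gnn_encoder import GnnConfig
        from dualdta.seq_encoder import EncoderConfig

        ds = gen_dataset(
            32, 16, 1.0, PlantedAffinityModel(noise_sd=0.0), seed=5
        )  # 512 records
        pairs = prepare_pairs(ds)
        cfg = ModelConfig(
            encoder=EncoderConfig(
                embed_dim=16, lstm_layers=1, heads=2, gem_groups=2, dropout=0.0
            ),
            gnn=GnnConfig(n_layers=1, hidden_dim=16),
            head_hidden=16,
        )
        model = DTAModel(cfg, seed=0)
        tc = TrainConfig(warmup_epochs=5, joint_epochs=1, lr=2e-3, batch_size=64, seed=0)
        history = train_warmup(model, pairs, tc)
        y = np.array([p.affinity for p in pairs])
        assert history[-1] < np.var(y)

    def test_fixed_seed_reproduces_loss_trajectory(self, tiny_model_config, tiny_pairs):
        tc = TrainConfig(warmup_epochs=2, joint_epochs=1, lr=1e-3, batch_size=16, seed=4)
        h1 = train_warmup(DTAModel(tiny_model_config, seed=2), tiny_pairs[:24], tc)
        h2 = train_warmup(DTAModel(tiny_model_config, seed=2), tiny_pairs[:24], tc)
        assert h1 == h2


class TestJointTraining:
    def test_checkpoint_is_best_validation_epoch(self, tiny_model, tiny_pairs):
        tc = TrainConfig(warmup_epochs=0, joint_epochs=4, lr=1e-3, batch_size=16, seed=0)
        history = train_joint(tiny_model, tiny_pairs[:32], tiny_pairs[32:44], tc)
        val = np.array([p.affinity for p in tiny_pairs[32:44]])
        pred = tiny_model.predict(tiny_pairs[32:44])
        restored = float(np.mean((pred - val) ** 2))
        assert restored == pytest.approx(min(history["val_mse"]), abs=1e-9)
        assert history["best_val_mse"] == pytest.approx(min(history["val_mse"]))

    def test_skipping_warmup_runs(self, tiny_model, tiny_pairs):
        tc = TrainConfig(warmup_epochs=0, joint_epochs=1, lr=1e-3, batch_size=16, seed=0)
        history = train_model(tiny_model, tiny_pairs[:24], tiny_pairs[24:30], tc)
        assert history["warmup_mse"] == []
        assert len(history["train_mse"]) == 1


class TestSplits:
    def _records(self, n_drugs=10, n_targets=10):
        from dualdta.synthetic import AffinityRecord

        return [
            AffinityRecord(f"D{i}", "CC", f"T{j}", 1.0 * i + j)
            for i in range(n_drugs)
            for j in range(n_targets)
        ]

    def test_random_cv_each_record_tested_exactly_once(self):
        records = self._records()
        folds = make_splits(records, SplitSpec(mode="random_cv", seed=0))
        seen = np.concatenate([f.test for f in folds])
        assert sorted(seen) == list(range(len(records)))
        for f in folds:
            all_idx = np.concatenate([f.train, f.val, f.test])
            assert len(np.unique(all_idx)) == len(records)
            assert abs(len(f.train) / len(records) - 0.7) < 0.05
            assert abs(len(f.val) / len(records) - 0.1) < 0.05

    def test_unseen_drug_disjointness(self):
        records = self._records()
        folds = make_splits(records, SplitSpec(mode="unseen_drug", seed=1))
        for f in folds:
            train_drugs = {records[i].drug_id for i in f.train}
            val_drugs = {records[i].drug_id for i in f.val}
            test_drugs = {records[i].drug_id for i in f.test}
            assert not (train_drugs & test_drugs)
            assert not (train_drugs & val_drugs)

    def test_unseen_target_disjointness(self):
        records = self._records()
        folds = make_splits(records, SplitSpec(mode="unseen_target", seed=1))
        for f in folds:
            train_t = {records[i].target_id for i in f.train}
            assert not (train_t & {records[i].target_id for i in f.test})
            assert not (train_t & {records[i].target_id for i in f.val})

    def test_all_unseen_exhaustive_audit_on_full_grid(self):
        records = self._records(10, 10)
        folds = make_splits(records, SplitSpec(mode="all_unseen", seed=2))
        for f in folds:
            train_d = {records[i].drug_id for i in f.train}
            train_t = {records[i].target_id for i in f.train}
            for i in f.test:
                assert records[i].drug_id not in train_d
                assert records[i].target_id not in train_t
            for i in f.val:
                assert records[i].drug_id not in train_d
                assert records[i].target_id not in train_t
            # straddling pairs must have been discarded, never reassigned
            kept = set(f.train) | set(f.val) | set(f.test)
            assert len(kept) < len(records)

    def test_seed_reproducibility(self):
        records = self._records()
        for mode in ("random_cv", "unseen_drug", "unseen_target", "all_unseen"):
            a = make_splits(records, SplitSpec(mode=mode, seed=7))
            b = make_splits(records, SplitSpec(mode=mode, seed=7))
            for fa, fb in zip(a, b):
                np.testing.assert_array_equal(fa.train, fb.train)
                np.testing.assert_array_equal(fa.val, fb.val)
                np.testing.assert_array_equal(fa.test, fb.test)

    def test_too_few_entities_rejected_with_counts(self):
        records = self._records(3, 10)
        with pytest.raises(ValueError, match="3"):
            make_splits(records, SplitSpec(mode="unseen_drug", seed=0))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(mode="bogus")
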