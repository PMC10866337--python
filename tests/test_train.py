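"""Training loop, early stopping, ensembling, and evaluation."""

import numpy as np
import pytest

from kinsolv.curation import SplitAssignment, make_random_split, make_reaction_split
from kinsolv.errors import ShapeError, UsageError
from kinsolv.network import new_bundle, predict_records
from kinsolv.synthetic import SurrogateParams, fixture_dataset
from kinsolv.train import (
    TrainConfig,
    build_ensemble,
    evaluate,
    finetune_epoch_sweep,
    member_seed,
    train,
)

from conftest import H_ABSTRACTION, make_record


@pytest.fixture(scope="module")
def train_set():
    return fixture_dataset(12, 4, SurrogateParams(noise_sd=0.1, seed=0), seed=1)


@pytest.fixture(scope="module")
def train_split(train_set):
    return make_reaction_split(train_set, test_frac=0.1, val_frac=0.2, seed=0)


SMALL = dict(hidden=16, depth=2, ffn_hidden=(16,), batch_size=16)


class TestTrain:
    def test_single_record_overfit(self):
        records = [
            make_record(H_ABSTRACTION, "O", 1.5, 2.5, record_id="t"),
            make_record(H_ABSTRACTION, "CCO", 1.0, 1.0, record_id="v"),
        ]
        split = SplitAssignment(roles=np.array(["train", "val"]))
        config = TrainConfig(max_epochs=400, batch_size=1, hidden=16, depth=1,
                             ffn_hidden=(16,), dropout=0.0, seed=0)
        _, history = train(records, split, config)
        assert min(history.train_loss) < 1e-3

    def test_deterministic_history(self, train_set, train_split):
        config = TrainConfig(max_epochs=3, seed=42, **SMALL)
        _, h1 = train(train_set, train_split, config)
        _, h2 = train(train_set, train_split, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_loss_decreases_early(self, train_set, train_split):
        config = TrainConfig(max_epochs=6, seed=0, **SMALL)
        _, history = train(train_set, train_split, config)
        assert history.train_loss[-1] < history.train_loss[0]

    def test_best_epoch_is_argmin_and_bundle_matches(self, train_set, train_split):
        config = TrainConfig(max_epochs=5, seed=1, **SMALL)
        bundle, history = train(train_set, train_split, config)
        assert history.best_epoch == int(np.argmin(history.val_loss))
        # returned parameters reproduce the minimum of the stored sequence
        val_records = [train_set[i] for i in train_split.indices("val")]
        preds = bundle.normalize(predict_records(val_records, bundle))
        y = bundle.normalize(np.stack([r.targets for r in val_records]))
        loss = float(((preds - y) ** 2).sum(axis=1).mean())
        assert loss == pytest.approx(min(history.val_loss), rel=1e-9)

    def test_zero_epochs_rejected(self):
        with pytest.raises(UsageError):
            TrainConfig(max_epochs=0)

    def test_one_epoch_changes_weights(self, train_set, train_split):
        init = new_bundle(hidden=16, depth=2, ffn_hidden=(16,), seed=3)
        init.target_std = np.array([2.0, 3.0])
        config = TrainConfig(max_epochs=1, seed=3, **SMALL)
        bundle, _ = train(train_set, train_split, config, init=init)
        assert not np.allclose(bundle.head.weights[0], init.head.weights[0])

    def test_empty_finetune_set_rejected(self, train_set):
        roles = np.full(len(train_set), "test", dtype="<U5")
        split = SplitAssignment(roles=roles)
        with pytest.raises(UsageError):
            train(train_set, split, TrainConfig(max_epochs=1, **SMALL))

    def test_init_shape_mismatch_rejected(self, train_set, train_split):
        init = new_bundle(hidden=16, depth=2, ffn_hidden=(16,), extras_dim=4, seed=0)
        with pytest.raises(ShapeError):
            train(train_set, train_split, TrainConfig(max_epochs=1, **SMALL), init=init)


class TestEnsemble:
    def test_folds_times_members(self, train_set):
        folds = [make_reaction_split(train_set, test_frac=0.1, seed=s) for s in (0, 1)]
        config = TrainConfig(max_epochs=1, ensemble_size=3, seed=0, **SMALL)
        bundles = build_ensemble(train_set, folds, config)
        assert len(bundles) == 6
        seeds = {b.seed for b in bundles}
        assert len(seeds) == 6  # all members distinctly seeded

    def test_single_member(self, train_set, train_split):
        config = TrainConfig(max_epochs=1, ensemble_size=1, seed=0, **SMALL)
        bundles = build_ensemble(train_set, [train_split], config)
        assert len(bundles) == 1

    def test_duplicate_seeds_duplicate_bundles(self, train_set, train_split):
        config = TrainConfig(max_epochs=2, ensemble_size=1, seed=5, **SMALL)
        b1 = build_ensemble(train_set, [train_split], config)[0]
        b2 = build_ensemble(train_set, [train_split], config)[0]
        for k, v in b1.param_arrays().items():
            np.testing.assert_array_equal(v, b2.param_arrays()[k])

    def test_member_seed_stable_and_bounded(self):
        assert member_seed(0, 1, 2) == member_seed(0, 1, 2)
        assert member_seed(0, 1, 2) != member_seed(0, 2, 1)
        assert 0 <= member_seed(123, 4, 4) < 2**31


class TestEvaluate:
    def test_perfect_predictor_zero_error(self, train_set):
        bundle = new_bundle(hidden=8, depth=1, ffn_hidden=(8,), seed=0)
        for w in bundle.head.weights:
            w[:] = 0.0
        records = [make_record(H_ABSTRACTION, "O", 1.25, -0.5)] * 4
        bundle.target_mean = np.array([1.25, -0.5])  # constant = the target
        metrics = evaluate([bundle], records)
        assert metrics["ddG_mae"] == 0.0 and metrics["ddH_rmse"] == 0.0

    def test_constant_zero_predictor_mae_is_mean_abs_target(self, train_set):
        bundle = new_bundle(hidden=8, depth=1, ffn_hidden=(8,), seed=0)
        for w in bundle.head.weights:
            w[:] = 0.0
        records = train_set[:40]
        metrics = evaluate([bundle], records)
        expected = sum(abs(r.ddG298) for r in records) / len(records)
        assert metrics["ddG_mae"] == pytest.approx(expected)

    def test_rmse_at_least_mae(self, train_set, train_split):
        config = TrainConfig(max_epochs=2, seed=0, **SMALL)
        bundle, _ = train(train_set, train_split, config)
        test = [train_set[i] for i in train_split.indices("test")]
        m = evaluate([bundle], test)
        assert m["ddG_rmse"] >= m["ddG_mae"]
        assert m["ddH_rmse"] >= m["ddH_mae"]

    def test_log10_unit_conversion(self, train_set):
        bundle = new_bundle(hidden=8, depth=1, ffn_hidden=(8,), seed=0)
        kcal = evaluate([bundle], train_set[:10])
        log10 = evaluate([bundle], train_set[:10], unit="log10")
        assert log10["ddG_mae"] == pytest.approx(kcal["ddG_mae"] / 1.3635606569988366)

    def test_empty_records_rejected(self):
        bundle = new_bundle(hidden=8, depth=1, ffn_hidden=(8,), seed=0)
        with pytest.raises(UsageError):
            evaluate([bundle], [])


class TestEpochSweep:
    def test_epoch_zero_row_equals_pretrained(self, train_set, train_split):
        config = TrainConfig(max_epochs=2, seed=0, **SMALL)
        pretrained, _ = train(train_set, train_split, config)
        holdout = [train_set[i] for i in train_split.indices("test")]
        ft_records = [train_set[i] for i in train_split.indices("train")]
        ft_records += [train_set[i] for i in train_split.indices("val")]
        ft_split = make_random_split(ft_records, val_frac=0.25, seed=1)
        rows = finetune_epoch_sweep(pretrained, ft_records, ft_split, holdout,
                                    [0, 1], config)
        base = evaluate([pretrained], holdout)
        assert rows[0]["holdout_ddG_mae"] == pytest.approx(base["ddG_mae"])
        assert rows[0]["max_epochs"] == 0.0
        assert len(rows) == 2
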