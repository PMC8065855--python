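"""Focal loss, class weights, schedules, AMSGrad, folds, two-stage training."""

import copy

import numpy as np
import pytest

from conftest import make_label_recording
from hypnonet.io import EpochDataset
from hypnonet.model import ModelConfig, SleepNet
from hypnonet.nn import Tensor
from hypnonet.sampling import SamplerConfig
from hypnonet.train import (
    AMSGrad,
    FocalLossParams,
    TrainSchedule,
    finetune,
    focal_loss,
    focal_loss_tensor,
    make_alpha_from_frequencies,
    pretrain,
    subject_kfold_split,
)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(40, 5))
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        labels = rng.integers(0, 5, size=40)
        fl = focal_loss(probs, labels,
                        FocalLossParams(alpha=np.ones(5), gamma=0.0))
        ce = -np.mean(np.log(probs[np.arange(40), labels]))
        assert abs(fl - ce) < 1e-9

    def test_perfect_prediction_gives_zero(self):
        probs = np.eye(5)[[0, 3]]
        assert focal_loss(probs, [0, 3], FocalLossParams()) == 0.0

    def test_hand_evaluated_single_sample(self):
        # p = 0.5, alpha = 1, gamma = 2 -> 0.25 * ln 2
        probs = np.array([[0.5, 0.5, 0.0, 0.0, 0.0]])
        out = focal_loss(probs, [0], FocalLossParams(alpha=np.ones(5), gamma=2.0))
        assert abs(out - 0.173286795139986327) < 1e-12

    def test_nonnegative_and_monotone_in_true_probability(self):
        params = FocalLossParams(gamma=2.0)
        grid = np.linspace(0.01, 0.99, 50)
        losses = []
        for p in grid:
            probs = np.array([[p, 1 - p, 0, 0, 0]])
            losses.append(focal_loss(probs, [0], params))
        losses = np.array(losses)
        assert (losses >= 0).all()
        assert (np.diff(losses) < 0).all()

    def test_downweights_easy_samples_relative_to_cross_entropy(self):
        def ratio(p):
            probs = np.array([[p, 1 - p, 0, 0, 0]])
            fl = focal_loss(probs, [0], FocalLossParams(gamma=2.0))
            ce = focal_loss(probs, [0], FocalLossParams(gamma=0.0))
            return fl / ce

        assert ratio(0.9) < ratio(0.1)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            focal_loss(np.full((1, 5), 0.2), [7], FocalLossParams())

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.normal(size=(6, 5)), requires_grad=True)
        labels = np.array([0, 1, 2, 3, 4, 2])
        params = FocalLossParams(alpha=rng.uniform(0.5, 2.0, 5), gamma=2.0)

        def f():
            return float(
                focal_loss_tensor(logits.softmax(-1), labels, params).data)

        loss = focal_loss_tensor(logits.softmax(-1), labels, params)
        loss.backward()
        eps = 1e-6
        for i in [(0, 0), (2, 3), (5, 2)]:
            logits.data[i] += eps
            fp = f()
            logits.data[i] -= 2 * eps
            fm = f()
            logits.data[i] += eps
            assert abs((fp - fm) / (2 * eps) - loss_grad(logits, i)) < 1e-7


def loss_grad(t, i):
    return t.grad[i]


class TestAlphaWeights:
    def test_reference_imbalance_ordering(self):
        counts = [7927, 2804, 17799, 5703, 7717]
        alpha = make_alpha_from_frequencies(counts)
        assert np.argmax(alpha) == 1   # N1, rarest, weighted highest
        assert np.argmin(alpha) == 2   # N2, most common, weighted lowest
        assert abs(alpha.mean() - 1.0) < 1e-12

    def test_equal_counts_give_unit_weights(self):
        assert np.allclose(make_alpha_from_frequencies([5, 5, 5]), 1.0)

    def test_two_class_inverse_proportion(self):
        alpha = make_alpha_from_frequencies([1, 3])
        assert np.allclose(alpha / alpha[1], [3.0, 1.0])
        assert abs(alpha.mean() - 1.0) < 1e-12

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            make_alpha_from_frequencies([4, 0, 2])


class TestSchedules:
    def test_pretrain_reference_trace(self):
        sched = TrainSchedule.pretrain_default()
        trace = [sched.lr_at(p) for p in range(1, 81)]
        assert trace == [1e-3] * 40 + [1e-4] * 40
        assert sched.batch_size == 256

    def test_finetune_reference_trace(self):
        sched = TrainSchedule.finetune_default()
        trace = [sched.lr_at(p) for p in range(1, 41)]
        assert trace == [1e-3] * 10 + [1e-4] * 10 + [5e-5] * 10 + [1e-5] * 10
        assert sched.subnet_lr == 1e-6
        assert sched.batch_size == 10
        assert (sched.beta1, sched.beta2) == (0.9, 0.99)

    def test_increasing_rates_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            TrainSchedule(lr_initial=1e-4, lr_steps=((5, 1e-3),),
                          passes_total=10)

    def test_passes_must_reach_last_step(self):
        with pytest.raises(ValueError, match="passes_total"):
            TrainSchedule(lr_steps=((40, 1e-4),), passes_total=30)


class TestAMSGrad:
    def test_max_second_moment_is_monotone(self):
        rng = np.random.default_rng(0)
        p = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        opt = AMSGrad([{"params": [p], "lr": 1e-2}])
        prev = None
        for step in range(20):
            p.grad = rng.normal(size=(4, 3)) * (1.0 / (step + 1))
            opt.step()
            vhat = opt.max_second_moment()[id(p)]
            if prev is not None:
                assert (vhat >= prev - 1e-18).all()
            prev = vhat

    def test_descends_a_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = AMSGrad([{"params": [p], "lr": 0.1}])
        for _ in range(300):
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestSubjectKFold:
    def test_twenty_subjects_twenty_folds_disjoint(self):
        subjects = [f"SC4{n:02d}" for n in range(20)]
        spec = subject_kfold_split(subjects, k=20, seed=0)
        sizes = [len(spec.fold_subjects(f)) for f in range(20)]
        assert sizes == [1] * 20
        for f in range(20):
            train, test = spec.split(f)
            assert set(train) & set(test) == set()
            assert sorted(train + test) == sorted(subjects)

    def test_round_robin_sizes(self):
        spec = subject_kfold_split([f"s{i}" for i in range(7)], k=3, seed=1)
        sizes = sorted((len(spec.fold_subjects(f)) for f in range(3)),
                       reverse=True)
        assert sizes == [3, 2, 2]

    def test_single_fold_holds_everyone(self):
        spec = subject_kfold_split(["a", "b", "c"], k=1, seed=0)
        assert spec.fold_subjects(0) == ["a", "b", "c"]

    def test_deterministic_in_seed(self):
        ids = [f"s{i}" for i in range(9)]
        a = subject_kfold_split(ids, 4, seed=7)
        b = subject_kfold_split(ids, 4, seed=7)
        assert a.assignments == b.assignments

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError, match="k must lie"):
            subject_kfold_split(["a", "b"], k=3, seed=0)


class TestPretrain:
    def test_separable_two_class_accuracy(self, separable_two_class_ds,
                                          tiny_cfg):
        sched = TrainSchedule.pretrain_default(passes_total=30, batch_size=32,
                                               seed=0)
        res = pretrain(separable_two_class_ds, tiny_cfg, sched,
                       FocalLossParams())
        assert res.acc_trace[-1] >= 0.95
        assert len(res.loss_trace) == 30

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_descends(self, separable_two_class_ds, tiny_cfg, seed):
        sched = TrainSchedule.pretrain_default(passes_total=10, batch_size=32,
                                               seed=seed)
        res = pretrain(separable_two_class_ds, tiny_cfg, sched,
                       FocalLossParams())
        assert res.loss_trace[9] < res.loss_trace[0]

    def test_empty_dataset_rejected(self, tiny_cfg):
        ds = EpochDataset(np.empty((0, 3000)), np.empty(0, dtype=int),
                          np.empty(0, dtype=object))
        with pytest.raises(ValueError, match="empty"):
            pretrain(ds, tiny_cfg, TrainSchedule.pretrain_default(
                passes_total=1), FocalLossParams())

    def test_reproducible_loss_trace(self, separable_two_class_ds, tiny_cfg):
        sched = TrainSchedule.pretrain_default(passes_total=3, batch_size=32,
                                               seed=5)
        a = pretrain(separable_two_class_ds, tiny_cfg, sched, FocalLossParams())
        b = pretrain(separable_two_class_ds, tiny_cfg, sched, FocalLossParams())
        assert np.allclose(a.loss_trace, b.loss_trace, atol=1e-5)


@pytest.fixture(scope="module")
def pretrained(small_training_recordings, tiny_cfg):
    from hypnonet.io import segment_epochs
    from hypnonet.sampling import class_balance_upsample

    dss = [segment_epochs(r) for r in small_training_recordings[:3]]
    ds = EpochDataset(
        np.concatenate([d.epochs for d in dss]),
        np.concatenate([d.labels for d in dss]),
        np.concatenate([d.subject_ids for d in dss]))
    counts = np.maximum(ds.class_counts(), 1)
    loss = FocalLossParams(alpha=make_alpha_from_frequencies(counts))
    ds = class_balance_upsample(ds, rng_seed=0)
    sched = TrainSchedule.pretrain_default(passes_total=8, batch_size=64,
                                           seed=0)
    return pretrain(ds, tiny_cfg, sched, loss), loss


class TestFinetune:
    def _validation_loss(self, model, rec, loss, L=10):
        spe = rec.samples_per_epoch
        tot, n = 0.0, 0
        for s in range(0, rec.n_epochs - L + 1, L):
            x = Tensor(rec.signal[s * spe:(s + L) * spe].reshape(1, L, spe))
            probs = model.forward_full(x).softmax(axis=-1)
            tot += float(focal_loss_tensor(
                probs, rec.epoch_labels[None, s:s + L], loss).data) * L
            n += L
        return tot / n

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_improves_sequence_level_validation_loss(
            self, pretrained, small_training_recordings, seed):
        pre, loss = pretrained
        val_rec = small_training_recordings[3]
        frozen = copy.deepcopy(pre.model)
        before = self._validation_loss(frozen, val_rec, loss)
        model = copy.deepcopy(pre.model)
        sched = TrainSchedule.finetune_default(passes_total=4, batch_size=4,
                                               seed=seed)
        fin = finetune(small_training_recordings[:3], model, sched, loss,
                       SamplerConfig(seq_len=10, rng_seed=seed))
        after = self._validation_loss(fin.model, val_rec, loss)
        assert after < before

    def test_two_learning_rate_groups(self, pretrained,
                                      small_training_recordings):
        pre, loss = pretrained
        model = copy.deepcopy(pre.model)
        sched = TrainSchedule.finetune_default(passes_total=1, batch_size=4,
                                               seed=0)
        fin = finetune(small_training_recordings[:3], model, sched, loss,
                       SamplerConfig(seq_len=10, rng_seed=0))
        assert fin.lr_trace[0] == {"subnet": 1e-6, "sequence": 1e-3}

    def test_augmentation_only_wired_into_pretraining(self):
        import inspect

        from hypnonet import train as train_mod

        assert "augment_batch(" not in inspect.getsource(train_mod.finetune)
        assert "augment_batch(" in inspect.getsource(train_mod.pretrain)
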