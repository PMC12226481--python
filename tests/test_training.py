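"""Cross-validation machinery, metrics, t-test, training contracts."""

import numpy as np
import pytest

from fnssir.epochs import EpochSet
from fnssir.model import FNSSIR, ModelConfig, ablate
from fnssir.plane import build_grid
from fnssir.simulate import SyntheticConfig, generate_dataset, generate_subjects
from fnssir.training import (DegenerateTTestError, EvalReport, TrainConfig,
                             chance_bounds, evaluate, label_shuffled,
                             loso_experiment, paired_ttest, stratified_kfold,
                             train)

TINY_MODEL = dict(T=100, pools=((3, 3, 5), (3, 3, 2)), msstcn_filters=(1, 1))


def tiny_epochs(rng, n=12, t=100, channels=None):
    channels = channels or list(
        __import__("fnssir.simulate", fromlist=["DEFAULT_CHANNELS"]).DEFAULT_CHANNELS)
    labels = np.tile([0, 1, 2], n // 3)
    return EpochSet(rng.standard_normal((n, len(channels), t)), labels,
                    channels, 100.0)


class TestStratifiedKFold:
    def test_126_balanced_labels(self):
        labels = np.repeat([0, 1, 2], 42)
        folds = stratified_kfold(labels, 4, seed=0)
        sizes = [len(te) for _, te in folds]
        assert sum(sizes) == 126
        for _, te in folds:
            counts = np.bincount(labels[te], minlength=3)
            assert set(counts) <= {10, 11}

    def test_disjoint_and_covering(self):
        labels = np.repeat([0, 1], 10)
        folds = stratified_kfold(labels, 5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(20))
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0

    def test_leave_one_out_singletons(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        # per-class leave-one-out: k equals the smallest class size
        folds = stratified_kfold(labels, 3, seed=0)
        assert all(len(te) == 2 for _, te in folds)

    def test_two_seeds_differ_but_stay_valid(self):
        labels = np.repeat([0, 1, 2], 8)
        a = stratified_kfold(labels, 4, seed=1)
        b = stratified_kfold(labels, 4, seed=2)
        assert any(not np.array_equal(x[1], y[1]) for x, y in zip(a, b))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="class 1"):
            stratified_kfold(np.array([0, 0, 0, 0, 1, 1]), 4, seed=0)


class TestEvalReport:
    def test_consistency_enforced(self):
        good = EvalReport(50.0, np.array([[1, 1], [1, 1]]), 4)
        good.validate()
        bad = EvalReport(80.0, np.array([[1, 1], [1, 1]]), 4)
        with pytest.raises(ValueError):
            bad.validate()

    def test_evaluate_accuracy_equals_confusion_trace(self, rng):
        ep = tiny_epochs(rng)
        model = FNSSIR(ModelConfig(**TINY_MODEL), seed=0)
        grid = build_grid(ep.channel_names)
        rep = evaluate(model, ep, grid)
        assert rep.accuracy == pytest.approx(
            100.0 * np.trace(rep.confusion) / rep.confusion.sum())

    def test_empty_test_set_rejected(self, rng):
        ep = tiny_epochs(rng).select_trials(np.array([], dtype=int))
        model = FNSSIR(ModelConfig(**TINY_MODEL), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, ep, build_grid(tiny_epochs(rng).channel_names))


class TestPairedTTest:
    def test_matches_scipy_closed_form(self, rng):
        from scipy.stats import ttest_rel

        a = rng.normal(80, 5, 15)
        b = rng.normal(78, 5, 15)
        t, p = paired_ttest(a, b)
        ref = ttest_rel(a, b)
        assert abs(t - ref.statistic) < 1e-9
        assert abs(p - ref.pvalue) < 1e-9

    def test_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateTTestError):
            paired_ttest([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])

    def test_symmetric_differences_give_t0_p1(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [2.0, 1.0])


class TestTrain:
    def test_zero_lr_freezes_weights_and_loss(self, rng):
        ep = tiny_epochs(rng)
        model = FNSSIR(ModelConfig(**TINY_MODEL, dropout_p=0.0), seed=0)
        grid = build_grid(ep.channel_names)
        before = [p.value.copy() for p in model.params()]
        res = train(model, ep, grid,
                    TrainConfig(epochs=3, lr=0.0, batch_size=12,
                                lambda_recon=0.0, seed=0))
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)
        assert np.ptp(res.loss_trace) < 1e-6

    def test_same_seed_reproduces_loss_trace(self, rng):
        ep = tiny_epochs(rng)
        grid = build_grid(ep.channel_names)
        traces = []
        for _ in range(2):
            model = FNSSIR(ModelConfig(**TINY_MODEL), seed=5)
            res = train(model, ep, grid,
                        TrainConfig(epochs=2, batch_size=4, seed=5))
            traces.append(res.loss_trace)
        assert traces[0] == traces[1]

    def test_loss_decreases_on_learnable_data(self):
        ep = generate_dataset(SyntheticConfig(n_trials_per_class=6, seed=2))
        from fnssir.epochs import crop, resample_to

        ep = crop(ep, 0.0, 12.0)
        ep = EpochSet(resample_to(ep.data, 100.0, 25.0), ep.labels,
                      ep.channel_names, 25.0)
        cfg = ModelConfig(T=300, msstcn_filters=(1, 1))
        model = FNSSIR(cfg, seed=0)
        grid = build_grid(ep.channel_names)
        res = train(model, ep, grid, TrainConfig(epochs=5, batch_size=6, seed=0))
        assert res.loss_trace[-1] < res.loss_trace[0]


class TestLOSO:
    def test_partition_and_reports(self):
        subs = generate_subjects(SyntheticConfig(n_trials_per_class=2, seed=8),
                                 n_subjects=3)
        cfg = ablate(ModelConfig(T=1400, msstcn_filters=(1, 1)), "MSSTCN")
        reports = loso_experiment(subs, cfg,
                                  TrainConfig(epochs=1, batch_size=4, seed=0,
                                              lambda_recon=0.0))
        assert set(reports) == {"S01", "S02", "S03"}
        for s in subs:
            assert reports[s.subject_id].n_test == s.n_trials

    def test_single_subject_rejected(self):
        subs = generate_subjects(SyntheticConfig(n_trials_per_class=2, seed=8),
                                 n_subjects=1)
        with pytest.raises(ValueError):
            loso_experiment(subs, ModelConfig(**TINY_MODEL), TrainConfig())


def test_label_shuffle_preserves_counts(rng):
    ep = tiny_epochs(rng)
    shuf = label_shuffled(ep, seed=4)
    assert np.array_equal(np.bincount(shuf.labels), np.bincount(ep.labels))
    assert not np.array_equal(shuf.labels, ep.labels)


def test_chance_bounds_contain_chance():
    lo, hi = chance_bounds(31, 3)
    assert lo < 100.0 / 3 < hi
    # pooling all 126 shuffled test predictions tightens the band
    lo126, hi126 = chance_bounds(126, 3)
    assert lo < lo126 < 100.0 / 3 < hi126 < hi
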