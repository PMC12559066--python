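"""Load categorisation, cross-validation splits, training behaviour,
test-time mirroring, metrics and the paired McNemar test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from liftload import training_eval as te
from liftload.kinematics import FeatureSequence, LiftInstance
from liftload.models import TransformerConfig
from liftload.training_eval import (
    LoadBinError,
    LoadCategory,
    TrainConfig,
    categorize_load,
    evaluate,
    mcnemar_test,
    predict_tta,
    split_intra_subject,
    split_loso,
    train,
)


class TestCategorizeLoad:
    @pytest.mark.parametrize(
        "kg, cat",
        [
            (2.7, LoadCategory.LIGHT), (4.1, LoadCategory.LIGHT), (5.4, LoadCategory.LIGHT),
            (6.8, LoadCategory.MEDIUM), (8.2, LoadCategory.MEDIUM), (9.5, LoadCategory.MEDIUM),
            (10.9, LoadCategory.HEAVY), (12.2, LoadCategory.HEAVY), (13.6, LoadCategory.HEAVY),
        ],
    )
    def test_study_loads_map_to_bins(self, kg, cat):
        assert categorize_load(kg) is cat

    @pytest.mark.parametrize("kg", [6.0, 10.0, 0.5, 20.0, -1.0])
    def test_out_of_bin_loads_rejected(self, kg):
        with pytest.raises(LoadBinError):
            categorize_load(kg)


def _toy_instances(n_subjects=4, per_subject=6, T=12, seed=0):
    """Tiny labelled instances with no real structure (split tests only)."""
    rng = np.random.default_rng(seed)
    loads = [2.7, 5.4, 6.8, 9.5, 10.9, 13.6]
    out = []
    for s in range(n_subjects):
        for i in range(per_subject):
            load = loads[i % len(loads)]
            out.append(
                LiftInstance(
                    features=FeatureSequence(values=rng.normal(size=(T, 47)), fps=30.0),
                    label=categorize_load(load),
                    subject_id=f"P{s}",
                    task="lift" if i % 2 == 0 else "lower",
                    posture=["mid-shin", "knuckle", "shoulder"][i % 3],
                    load_kg=load,
                )
            )
    return out


class TestSplitLoso:
    def test_one_fold_per_subject_partition(self):
        insts = _toy_instances(n_subjects=5)
        folds = split_loso(insts)
        assert len(folds) == 5
        seen = []
        for tr, ts in folds:
            test_subjects = {i.subject_id for i in ts}
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint({i.subject_id for i in tr})
            assert len(tr) + len(ts) == len(insts)
            seen.extend(id(i) for i in ts)
        assert len(seen) == len(insts) and len(set(seen)) == len(insts)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            split_loso(_toy_instances(n_subjects=1))


class TestSplitIntraSubject:
    def test_every_subject_in_both_sides(self, small_instances):
        folds = split_intra_subject(small_instances, n_folds=3, seed=0)
        subjects = {i.subject_id for i in small_instances}
        for tr, ts in folds:
            assert {i.subject_id for i in tr} == subjects
            assert {i.subject_id for i in ts} == subjects

    def test_train_share_close_to_two_thirds(self, small_instances):
        folds = split_intra_subject(small_instances, n_folds=3, seed=0)
        shares = [len(tr) / (len(tr) + len(ts)) for tr, ts in folds]
        assert all(0.60 <= s <= 0.72 for s in shares)

    def test_deterministic_given_seed(self, small_instances):
        a = split_intra_subject(small_instances, n_folds=3, seed=5)
        b = split_intra_subject(small_instances, n_folds=3, seed=5)
        for (tra, tsa), (trb, tsb) in zip(a, b):
            assert [id(i) for i in tsa] == [id(i) for i in tsb]

    def test_small_cells_train_only(self):
        insts = _toy_instances(n_subjects=3, per_subject=6)
        # each (subject, category, posture) cell here has 1 instance < 3 folds
        folds = split_intra_subject(insts, n_folds=3, seed=0)
        for tr, ts in folds:
            assert len(ts) == 0 or len(ts) < len(insts)
            assert len(tr) + len(ts) == len(insts)


class TestMcnemar:
    @staticmethod
    def _exact_oracle(b, c):
        """Independent enumeration of the exact two-sided binomial test."""
        n = b + c
        if n == 0:
            return 1.0
        m = min(b, c)
        tail = sum(Fraction(math.comb(n, k)) for k in range(m + 1)) / Fraction(2) ** n
        return float(min(1, 2 * tail))

    def test_balanced_discordance_gives_p_one(self):
        labels = np.zeros(10, int)
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([1] * 5 + [0] * 5)
        _, p = mcnemar_test(a, b, labels)
        assert p == pytest.approx(1.0)

    def test_one_sided_discordance_binomial(self):
        labels = np.zeros(8, int)
        a = np.zeros(8, int)      # all correct
        b = np.ones(8, int)       # all wrong
        _, p = mcnemar_test(a, b, labels)
        assert p == pytest.approx(2 * 0.5**8)  # 0.0078125

    def test_identical_predictions_give_p_one(self):
        labels = np.array([0, 1, 0, 1])
        preds = np.array([0, 1, 1, 1])
        stat, p = mcnemar_test(preds, preds, labels)
        assert (stat, p) == (0.0, 1.0)

    def test_matches_exact_enumeration_for_all_small_tables(self):
        for b in range(13):
            for c in range(13 - b):
                labels = np.zeros(b + c + 2, int)
                pa = np.array([0] * b + [1] * c + [0, 1])
                pb = np.array([1] * b + [0] * c + [0, 1])
                _, p = mcnemar_test(pa, pb, labels)
                assert p == pytest.approx(self._exact_oracle(b, c), abs=1e-12), (b, c)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test([0, 1], [0], [0, 1])


def _tiny_config(num_classes=2):
    return TransformerConfig(embed_dim=16, depth=1, heads=2, max_len=160,
                             num_classes=num_classes, dropout_path=0.0,
                             activation="relu", dtype="float32")


@pytest.fixture(scope="module")
def separable_instances():
    from liftload.synthetic import SimConfig, dataset_to_instances, generate_dataset

    cfg = SimConfig(n_subjects=4, seed=11, load_effect=0.5)
    return dataset_to_instances(generate_dataset(cfg))


class TestTrain:
    def test_deterministic_loss_curves(self, separable_instances):
        sub = te.filter_for_setting(separable_instances, "binary")[:40]
        tc = TrainConfig(epochs=3, warmup_epochs=1, seed=7)
        m1 = train(sub, _tiny_config(), tc)
        m2 = train(sub, _tiny_config(), tc)
        assert m1.loss_history == m2.loss_history  # bitwise

    def test_separable_data_reaches_high_training_accuracy(self, separable_instances):
        sub = te.filter_for_setting(separable_instances, "binary")
        tc = TrainConfig(epochs=28, warmup_epochs=2, lr=3e-3, seed=0)
        model = train(sub, _tiny_config(), tc)
        frag = evaluate(model, sub, "binary")
        assert frag.accuracy >= 0.95

    def test_permuted_labels_give_chance_heldout_accuracy(self, separable_instances):
        sub = te.filter_for_setting(separable_instances, "binary")
        folds = split_loso(sub)
        tr, ts = folds[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation([te.label_code(i.label, 2) for i in tr])
        tc = TrainConfig(epochs=3, warmup_epochs=1, lr=3e-3, seed=1)
        model = train(tr, _tiny_config(), tc, labels=perm)
        frag = evaluate(model, ts, "binary")
        sd = np.sqrt(0.25 / len(ts))
        assert abs(frag.accuracy - 0.5) <= 3 * sd

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], _tiny_config(), TrainConfig(epochs=2, warmup_epochs=1))

    def test_binary_training_rejects_medium(self, separable_instances):
        medium = [i for i in separable_instances if i.label == LoadCategory.MEDIUM]
        with pytest.raises(ValueError):
            train(medium[:8], _tiny_config(num_classes=2),
                  TrainConfig(epochs=2, warmup_epochs=1))


def test_paired_model_comparison_end_to_end(separable_instances):
    """Transformer vs CNN cross-validated and compared with McNemar."""
    from liftload.models import CNNConfig

    proto = te.ProtocolConfig(
        setting="binary",
        model_config=_tiny_config(),
        train_config=TrainConfig(epochs=3, warmup_epochs=1, lr=3e-3, seed=2),
    )
    rep_a = te.run_experiment(separable_instances, proto)
    proto_b = te.ProtocolConfig(
        setting="binary",
        model_kind="cnn",
        model_config=CNNConfig(width=16, num_classes=2, dtype="float32"),
        train_config=proto.train_config,
    )
    rep_b = te.run_experiment(separable_instances, proto_b)
    # pooled predictions are aligned instance-by-instance across reports
    pd.testing.assert_frame_equal(
        rep_a.predictions[["subject_id", "true"]],
        rep_b.predictions[["subject_id", "true"]],
    )
    stat, p = mcnemar_test(rep_a.predictions["pred"], rep_b.predictions["pred"],
                           rep_a.predictions["true"])
    assert 0.0 <= p <= 1.0


class TestPredictTTA:
    def test_average_of_original_and_mirror(self, separable_instances):
        from liftload.kinematics import flip_features
        from liftload.training_eval import predict_proba

        sub = te.filter_for_setting(separable_instances, "binary")[:20]
        model = train(sub, _tiny_config(),
                      TrainConfig(epochs=2, warmup_epochs=1, seed=2))
        inst = sub[0]
        p = predict_tta(model, inst)
        p_orig = predict_proba(model, [inst.features])[0]
        p_flip = predict_proba(model, [flip_features(inst.features)])[0]
        np.testing.assert_allclose(p, 0.5 * (p_orig + p_flip), atol=1e-7)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_arithmetic_mean_example(self):
        np.testing.assert_allclose(
            0.5 * (np.array([0.8, 0.2]) + np.array([0.6, 0.4])), [0.7, 0.3]
        )


class TestEvaluate:
    def test_confusion_conservation(self, separable_instances):
        sub = te.filter_for_setting(separable_instances, "binary")[:30]
        model = train(sub, _tiny_config(),
                      TrainConfig(epochs=2, warmup_epochs=1, seed=3))
        frag = evaluate(model, sub, "binary")
        assert frag.confusion.sum() == len(sub)
        y = np.array([te.label_code(i.label, 2) for i in sub])
        np.testing.assert_array_equal(frag.confusion.sum(axis=1),
                                      np.bincount(y, minlength=2))

    def test_empty_test_set_rejected(self, separable_instances):
        sub = te.filter_for_setting(separable_instances, "binary")[:10]
        model = train(sub, _tiny_config(), TrainConfig(epochs=2, warmup_epochs=1))
        with pytest.raises(ValueError):
            evaluate(model, [], "binary")
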