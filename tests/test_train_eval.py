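"""Cold-start splitting, training dynamics and metric correctness."""

import numpy as np
import pytest

from mseddi import (
    DDIRecord,
    Drug,
    EventVocabulary,
    KGTriplet,
    ModelConfig,
    SynthConfig,
    TrainConfig,
    generate_bundle,
)
from mseddi.data import DatasetBundle
from mseddi.train import (
    cold_start_split,
    evaluate,
    evaluate_probs,
    train_model,
    pairs_to_arrays,
)

# ---------------------------------------------------------------------------
# independent metric oracles (brute force; never call sklearn)

def auc_pairwise(y: np.ndarray, s: np.ndarray) -> float:
    """Probability a random positive outranks a random negative, ties 0.5."""
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def ap_threshold(y: np.ndarray, s: np.ndarray) -> float:
    """Average precision by stepping through unique scores descending."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # group tied thresholds
            j += 1
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def f1_macro_bruteforce(y_true, y_pred, n_classes) -> float:
    f1s = []
    for c in range(n_classes):
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)  # absent class -> 0
    return float(np.mean(f1s))


def make_complete_bundle(n_drugs: int) -> DatasetBundle:
    """Complete DDI graph over n drugs with a single event."""
    drugs = [Drug(f"D{i}", "CC") for i in range(n_drugs)]
    ddis = [DDIRecord(f"D{i}", f"D{j}", 0)
            for i in range(n_drugs) for j in range(i + 1, n_drugs)]
    trips = [KGTriplet(f"D{i}", "r", "hub") for i in range(n_drugs)]
    return DatasetBundle(drugs, ddis, trips, EventVocabulary(["e0"]), [])


# ---------------------------------------------------------------------------

class TestColdStartSplit:
    def test_new_sets_partition_drugs(self):
        bundle = make_complete_bundle(10)
        folds = cold_start_split(bundle, 5, seed=0)
        news = [f.new_drugs for f in folds]
        assert all(len(n) == 2 for n in news)
        assert set().union(*news) == set(bundle.drug_ids)
        assert sum(len(n) for n in news) == 10

    def test_complete_graph_pair_counts(self):
        """45 pairs over 10 drugs, 2 new per fold: C(8,2)=28 train,
        8*2=16 known-new, C(2,2)=1 new-new."""
        bundle = make_complete_bundle(10)
        for fold in cold_start_split(bundle, 5, seed=3):
            assert len(fold.train_pairs) == 28
            assert len(fold.task1_pairs) == 16
            assert len(fold.task2_pairs) == 1

    def test_same_seed_identical_splits(self):
        bundle = make_complete_bundle(12)
        f1 = cold_start_split(bundle, 4, seed=9)
        f2 = cold_start_split(bundle, 4, seed=9)
        for a, b in zip(f1, f2):
            assert a.new_drugs == b.new_drugs
            assert a.train_pairs == b.train_pairs

    def test_invariants_on_synthetic_bundles(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cfg = SynthConfig(
                n_drugs=int(rng.integers(8, 24)),
                n_classes=int(rng.integers(2, 5)),
                n_events=int(rng.integers(1, 4)),
                label_noise=float(rng.random() * 0.3),
                kg_noise_triplets=int(rng.integers(0, 30)),
                seed=int(rng.integers(2**31)),
            )
            bundle, _ = generate_bundle(cfg)
            k = int(rng.integers(2, 6))
            for fold in cold_start_split(bundle, k, seed=int(rng.integers(2**31))):
                fold.validate(bundle)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            cold_start_split(make_complete_bundle(3), 5, seed=0)


class TestMetrics:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 2, 1])
        probs = np.eye(3)[y]
        rep = evaluate_probs(y, probs, 3)
        assert rep.acc == rep.auc_micro == rep.aupr_micro == rep.f1_macro == 1.0

    def test_half_correct_accuracy(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.3, 0.7], [0.6, 0.4]])
        assert evaluate_probs(y, probs, 2).acc == 0.5

    def test_micro_auc_equals_concordant_pair_count(self):
        y = np.array([0, 1, 0])
        probs = np.array([[0.7, 0.3], [0.4, 0.6], [0.8, 0.2]])
        rep = evaluate_probs(y, probs, 2)
        onehot = np.eye(2)[y].ravel()
        assert rep.auc_micro == pytest.approx(
            auc_pairwise(onehot, probs.ravel()), abs=1e-12
        )

    def test_oracle_equivalence_random_instances(self):
        """Micro AUC/AUPR and macro F1 agree with brute-force pairwise /
        threshold-stepping / per-class oracles."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n, c = int(rng.integers(4, 12)), int(rng.integers(2, 5))
            y = rng.integers(c, size=n)
            y[0] = 0  # keep at least one fixed class
            probs = rng.random(size=(n, c))
            probs /= probs.sum(axis=1, keepdims=True)
            rep = evaluate_probs(y, probs, c)
            flat_y = np.eye(c)[y].ravel()
            flat_s = probs.ravel()
            assert rep.auc_micro == pytest.approx(auc_pairwise(flat_y, flat_s), abs=1e-9)
            assert rep.aupr_micro == pytest.approx(ap_threshold(flat_y, flat_s), abs=1e-9)
            assert rep.f1_macro == pytest.approx(
                f1_macro_bruteforce(y, probs.argmax(axis=1), c), abs=1e-9
            )

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_probs(np.array([]), np.zeros((0, 3)), 3)


@pytest.fixture()
def small_setup(study, features, splits):
    bundle, _ = study
    return bundle, features, splits[0]


class TestTraining:
    def test_loss_trace_decreases(self, small_setup):
        """10-epoch moving average of the loss is non-increasing on a
        majority of 3 seeds (network channel only for speed)."""
        bundle, feats, split = small_setup
        ok = 0
        for seed in (0, 1, 2):
            _, trace = train_model(
                split, feats, bundle,
                ModelConfig(dim=16, n_events=8, channel_mask=("network",),
                            seed=seed),
                TrainConfig(epochs=20, seed=seed),
            )
            assert np.all(np.isfinite(trace))
            ma = np.convolve(trace, np.ones(10) / 10, mode="valid")
            ok += bool(np.all(np.diff(ma) <= 1e-6))
        assert ok >= 2

    def test_weight_decay_changes_final_weights(self, small_setup):
        bundle, feats, split = small_setup
        cfg = ModelConfig(dim=16, n_events=8, channel_mask=("network",), seed=0)
        m1, _ = train_model(split, feats, bundle, cfg,
                            TrainConfig(epochs=2, weight_decay=0.0, seed=0))
        m2, _ = train_model(split, feats, bundle, cfg,
                            TrainConfig(epochs=2, weight_decay=1e-5, seed=0))
        diffs = [np.abs(a.data - b.data).max()
                 for a, b in zip(m1.parameters(), m2.parameters())]
        assert max(diffs) > 0

    def test_cold_start_contract_no_new_drug_touched(self, small_setup):
        """The trained model must never have queried a new drug."""
        bundle, feats, split = small_setup
        model, _ = train_model(
            split, feats, bundle,
            ModelConfig(dim=16, n_events=8, channel_mask=("network",), seed=0),
            TrainConfig(epochs=2, seed=0),
        )
        index = bundle.drug_index()
        known_idx = {index[d] for d in split.known_drugs}
        assert model.accessed_drugs <= known_idx

    def test_empty_train_pairs_rejected(self, small_setup):
        bundle, feats, split = small_setup
        import dataclasses

        empty = dataclasses.replace(split, train_pairs=[])
        with pytest.raises(ValueError):
            train_model(empty, feats, bundle,
                        ModelConfig(n_events=8), TrainConfig())

    def test_reverse_augmentation_doubles_batches(self, small_setup):
        bundle, feats, split = small_setup
        cfg = ModelConfig(dim=16, n_events=8, channel_mask=("network",), seed=0)
        m, _ = train_model(split, feats, bundle, cfg,
                           TrainConfig(epochs=1, seed=0, augment_reverse=True))
        assert m is not None  # runs; pair order coverage is doubled


def test_evaluate_on_fold(study, features, splits):
    """Metrics from an (untrained) model are well-formed and in range."""
    bundle, _ = study
    model_cfg = ModelConfig(dim=16, n_events=8, seed=0)
    from mseddi.model import MSEDDIModel

    model = MSEDDIModel(model_cfg)
    rep = evaluate(model, splits[0].task1_pairs, features, bundle)
    for v in rep.as_dict().values():
        assert 0.0 <= v <= 1.0
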