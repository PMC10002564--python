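"""Cold-start splitting, supervised training, and the metric suite.

The inductive protocol divides the *drugs* (not the pairs) into k folds:
in each fold one subset is "new" and the rest "known".  Pairs between two
known drugs form the training set; pairs with exactly one new drug form
the Task-1 test set; pairs between two new drugs form the Task-2 test
set.  The model is trained only on known-known pairs, so every test pair
involves at least one drug never seen with a label.

Unsupervised drug features (knowledge-graph vectors, notation embeddings,
molecular graphs) are pretrained once on all drugs: they use no event
labels, so sharing them across folds leaks nothing.

Metrics are the multi-class suite: top-1 accuracy (ties broken toward the
lowest index), micro-averaged AUC and AUPR over the flattened label
indicator matrix, macro F1 with absent classes contributing zero, and a
per-event one-vs-rest AUC/AUPR table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from ._tensor import Adam, cross_entropy
from .data import DatasetBundle, DDIRecord
from .kge import TransEConfig, extract_drug_kge, train_transe
from .model import DrugFeatures, ModelConfig, MSEDDIModel
from .molgraph import batch_graphs, smiles_to_molgraph
from .smiles import W2VConfig, notation_embeddings

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "MetricsReport",
    "cold_start_split",
    "prepare_features",
    "train_model",
    "evaluate",
    "evaluate_probs",
    "run_experiment",
    "write_predictions",
    "paper_train_config",
]


@dataclass
class FoldSplit:
    fold: int
    known_drugs: set[str]
    new_drugs: set[str]
    train_pairs: list[DDIRecord]
    task1_pairs: list[DDIRecord]
    task2_pairs: list[DDIRecord]

    def validate(self, bundle: DatasetBundle) -> None:
        """Assert every split invariant; raises AssertionError on violation."""
        all_drugs = set(bundle.drug_ids)
        assert not (self.known_drugs & self.new_drugs), "known/new overlap"
        assert self.known_drugs | self.new_drugs == all_drugs, "drugs lost"
        routed = len(self.train_pairs) + len(self.task1_pairs) + len(self.task2_pairs)
        assert routed == len(bundle.ddis), "pair lists do not partition the DDIs"
        for rec in self.train_pairs:
            assert rec.drug_i in self.known_drugs and rec.drug_j in self.known_drugs
        for rec in self.task1_pairs:
            assert (rec.drug_i in self.new_drugs) != (rec.drug_j in self.new_drugs)
        for rec in self.task2_pairs:
            assert rec.drug_i in self.new_drugs and rec.drug_j in self.new_drugs


@dataclass
class TrainConfig:
    """Desk-scale defaults; :func:`paper_train_config` gives the published
    full-scale schedule (loss weight 1e-5, batch 512, 350 epochs, lr 1e-4)."""

    weight_decay: float = 1e-5
    batch_size: int = 64
    epochs: int = 50
    lr: float = 1e-3
    cosine_decay: bool = True  # anneal lr to 0 so training settles
    seed: int = 0
    augment_reverse: bool = False

    def __post_init__(self):
        if self.weight_decay < 0 or self.batch_size < 1 or self.epochs < 0 or self.lr <= 0:
            raise ValueError("invalid training configuration")


def paper_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(weight_decay=1e-5, batch_size=512, epochs=350,
                       lr=1e-4, seed=seed)


@dataclass
class MetricsReport:
    acc: float
    aupr_micro: float
    auc_micro: float
    f1_macro: float
    per_event_auc: list[float] = field(default_factory=list)
    per_event_aupr: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "aupr_micro": self.aupr_micro,
                "auc_micro": self.auc_micro, "f1_macro": self.f1_macro}


# -- splitting -----------------------------------------------------------

def cold_start_split(bundle: DatasetBundle, k: int,
                     seed: int) -> list[FoldSplit]:
    """Shuffle drugs by seed, cut into k near-equal subsets, and route
    every DDI record by the membership of its two drugs."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    drug_ids = bundle.drug_ids
    if k > len(drug_ids):
        raise ValueError(f"cannot split {len(drug_ids)} drugs into {k} folds")
    rng = np.random.default_rng(seed)
    order = [drug_ids[i] for i in rng.permutation(len(drug_ids))]
    subsets = [set(chunk) for chunk in np.array_split(np.asarray(order, dtype=object), k)]
    folds = []
    for f, new in enumerate(subsets):
        known = set(drug_ids) - new
        train, task1, task2 = [], [], []
        for rec in bundle.ddis:
            n_new = (rec.drug_i in new) + (rec.drug_j in new)
            (train, task1, task2)[n_new].append(rec)
        folds.append(FoldSplit(f, known, new, train, task1, task2))
    return folds


# -- feature preparation -------------------------------------------------

def prepare_features(bundle: DatasetBundle,
                     kge_cfg: TransEConfig | None = None,
                     w2v_cfg: W2VConfig | None = None,
                     dtype=np.float32) -> DrugFeatures:
    """Pretrain the frozen unsupervised features for every drug."""
    kge_cfg = kge_cfg or TransEConfig()
    w2v_cfg = w2v_cfg or W2VConfig()
    table, _ = train_transe(bundle.triplets, kge_cfg)
    kge = extract_drug_kge(table, bundle.drug_ids).astype(dtype)
    sne, _, _ = notation_embeddings([d.smiles for d in bundle.drugs], w2v_cfg)
    graphs = batch_graphs([smiles_to_molgraph(d.smiles) for d in bundle.drugs],
                          dtype=dtype)
    return DrugFeatures(kge=kge, sne=sne.astype(dtype), graphs=graphs)


def pairs_to_arrays(records: list[DDIRecord], drug_index: dict[str, int]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i_idx = np.array([drug_index[r.drug_i] for r in records], dtype=int)
    j_idx = np.array([drug_index[r.drug_j] for r in records], dtype=int)
    y = np.array([r.event for r in records], dtype=int)
    return i_idx, j_idx, y


# -- training ------------------------------------------------------------

def train_model(split: FoldSplit, features: DrugFeatures,
                bundle: DatasetBundle, model_cfg: ModelConfig,
                train_cfg: TrainConfig) -> tuple[MSEDDIModel, list[float]]:
    """Minimize cross-entropy (+ L2 penalty of weight ``weight_decay``)
    over the known-known pairs only.  Returns the model and the per-epoch
    mean loss trace."""
    if not split.train_pairs:
        raise ValueError("empty training pair list")
    drug_index = bundle.drug_index()
    i_idx, j_idx, y = pairs_to_arrays(split.train_pairs, drug_index)
    if train_cfg.augment_reverse:
        i_idx, j_idx = np.concatenate([i_idx, j_idx]), np.concatenate([j_idx, i_idx])
        y = np.concatenate([y, y])
    model = MSEDDIModel(model_cfg)
    model.train()
    opt = Adam(model.parameters(), lr=train_cfg.lr,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    n = len(y)
    bs = train_cfg.batch_size
    trace = []
    for epoch in range(train_cfg.epochs):
        if train_cfg.cosine_decay:
            opt.lr = train_cfg.lr * 0.5 * (
                1.0 + np.cos(np.pi * epoch / train_cfg.epochs)
            )
        order = rng.permutation(n)
        starts = list(range(0, n, bs))
        # batch norm cannot digest a single-sample batch: fold a trailing
        # singleton into the previous batch
        if len(starts) > 1 and n - starts[-1] == 1:
            starts.pop()
        losses = []
        for s_i, start in enumerate(starts):
            stop = starts[s_i + 1] if s_i + 1 < len(starts) else n
            idx = order[start:stop]
            logits = model.forward_logits(i_idx[idx], j_idx[idx], features)
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


# -- metrics -------------------------------------------------------------

def evaluate_probs(y_true: np.ndarray, probs: np.ndarray,
                   n_events: int) -> MetricsReport:
    """Metric suite from a probability matrix (n_pairs × n_events)."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty pair list")
    onehot = np.zeros((len(y_true), n_events))
    onehot[np.arange(len(y_true)), y_true] = 1.0
    pred = probs.argmax(axis=1)  # argmax ties resolve to the lowest index
    acc = float((pred == y_true).mean())
    auc_micro = float(roc_auc_score(onehot.ravel(), probs.ravel()))
    aupr_micro = float(average_precision_score(onehot.ravel(), probs.ravel()))
    f1 = float(f1_score(y_true, pred, labels=np.arange(n_events),
                        average="macro", zero_division=0))
    per_auc, per_aupr = [], []
    for kcls in range(n_events):
        truth = onehot[:, kcls]
        if truth.min() == truth.max():  # class absent (or universal): undefined
            per_auc.append(float("nan"))
            per_aupr.append(float("nan"))
        else:
            per_auc.append(float(roc_auc_score(truth, probs[:, kcls])))
            per_aupr.append(float(average_precision_score(truth, probs[:, kcls])))
    return MetricsReport(acc, aupr_micro, auc_micro, f1, per_auc, per_aupr)


def evaluate(model: MSEDDIModel, pairs: list[DDIRecord],
             features: DrugFeatures, bundle: DatasetBundle) -> MetricsReport:
    if not pairs:
        raise ValueError("cannot evaluate an empty pair list")
    i_idx, j_idx, y = pairs_to_arrays(pairs, bundle.drug_index())
    probs = model.predict_proba(i_idx, j_idx, features)
    return evaluate_probs(y, probs, model.cfg.n_events)


# -- full experiment -----------------------------------------------------

@dataclass
class ExperimentResult:
    task1: list[MetricsReport]
    task2: list[MetricsReport | None]

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for task, reports in (("task1", self.task1), ("task2", self.task2)):
            reports = [r for r in reports if r is not None]
            for key in ("acc", "aupr_micro", "auc_micro", "f1_macro"):
                vals = [getattr(r, key) for r in reports]
                out.setdefault(task, {})[f"{key}_mean"] = float(np.mean(vals))
                out[task][f"{key}_sd"] = float(np.std(vals))
        return out


def run_experiment(bundle: DatasetBundle, k: int, model_cfg: ModelConfig,
                   train_cfg: TrainConfig,
                   kge_cfg: TransEConfig | None = None,
                   w2v_cfg: W2VConfig | None = None,
                   folds: list[int] | None = None) -> ExperimentResult:
    """Pretrain features, then train and evaluate each requested fold of
    the k-fold cold-start split (all folds by default)."""
    features = prepare_features(bundle, kge_cfg, w2v_cfg)
    splits = cold_start_split(bundle, k, seed=train_cfg.seed)
    task1, task2 = [], []
    for split in splits:
        if folds is not None and split.fold not in folds:
            continue
        model, _ = train_model(split, features, bundle, model_cfg, train_cfg)
        task1.append(evaluate(model, split.task1_pairs, features, bundle)
                     if split.task1_pairs else None)
        task2.append(evaluate(model, split.task2_pairs, features, bundle)
                     if split.task2_pairs else None)
    return ExperimentResult(task1, task2)


def write_predictions(path_prefix, pairs: list[DDIRecord],
                      bundle: DatasetBundle, probs: np.ndarray) -> None:
    """TSV of argmax predictions plus a per-class probability matrix."""
    events = bundle.events
    pred = probs.argmax(axis=1)
    out = Path(str(path_prefix) + "_predictions.tsv")
    with out.open("w", encoding="utf-8") as fh:
        for rec, p, row in zip(pairs, pred, probs):
            fh.write(f"{rec.drug_i}\t{rec.drug_j}\t{events.labels[p]}\t"
                     f"{row[p]:.6f}\n")
    mat = Path(str(path_prefix) + "_probabilities.tsv")
    with mat.open("w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\t" + "\t".join(events.labels) + "\n")
        for rec, row in zip(pairs, probs):
            fh.write(f"{rec.drug_i}\t{rec.drug_j}\t"
                     + "\t".join(f"{x:.6f}" for x in row) + "\n")
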