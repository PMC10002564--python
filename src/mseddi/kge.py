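"""Translational knowledge-graph embedding (TransE) for drug entities.

A relation is modelled as a vector translation: for a true triplet
``(h, r, t)`` the embeddings should satisfy ``h + r ≈ t``, scored by the
negative distance ``f(h, r, t) = -‖h + r - t‖``.  Training minimizes the
margin ranking loss ``max(0, γ - f(pos) + f(neg))`` over positive triplets
paired with corrupted negatives (head or tail replaced by a uniformly
drawn entity such that the corrupted triplet is not itself positive),
with entity vectors renormalized to unit L2 after every epoch, following
the original translational-embedding recipe.  The embedder is pretrained
on the whole KG and frozen; per-drug vectors are then screened out as the
network-channel input of the pair model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import KGTriplet

__all__ = [
    "TransEConfig",
    "KGEmbeddingTable",
    "SamplingError",
    "score_triplet",
    "corrupt_triplet",
    "margin_loss",
    "train_transe",
    "extract_drug_kge",
    "mean_tail_rank",
]


class SamplingError(RuntimeError):
    """No valid corrupted triplet could be drawn (degenerate KG)."""


@dataclass
class TransEConfig:
    dim_kge: int = 32
    margin: float = 1.0
    norm: str = "L2"
    lr: float = 0.01
    epochs: int = 500
    negatives_per_positive: int = 1
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.dim_kge < 1:
            raise ValueError("dim_kge must be >= 1")
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if self.norm not in ("L1", "L2"):
            raise ValueError("norm must be 'L1' or 'L2'")


@dataclass
class KGEmbeddingTable:
    """Entity and relation vectors plus their index maps."""

    entity_index: dict[str, int]
    relation_index: dict[str, int]
    entity_vectors: np.ndarray   # (n_entities, dim)
    relation_vectors: np.ndarray  # (n_relations, dim)

    @property
    def dim(self) -> int:
        return self.entity_vectors.shape[1]

    def entity(self, name: str) -> np.ndarray:
        return self.entity_vectors[self.entity_index[name]]

    def relation(self, name: str) -> np.ndarray:
        return self.relation_vectors[self.relation_index[name]]

    def save_tsv(self, entity_path, relation_path) -> None:
        for path, index, vecs in (
            (entity_path, self.entity_index, self.entity_vectors),
            (relation_path, self.relation_index, self.relation_vectors),
        ):
            with open(path, "w", encoding="utf-8") as fh:
                for name, i in index.items():
                    row = "\t".join(repr(float(x)) for x in vecs[i])
                    fh.write(f"{name}\t{row}\n")

    @classmethod
    def load_tsv(cls, entity_path, relation_path) -> "KGEmbeddingTable":
        def read(path):
            idx, rows = {}, []
            with open(path, "r", encoding="utf-8") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    idx[parts[0]] = len(rows)
                    rows.append([float(x) for x in parts[1:]])
            return idx, np.asarray(rows, dtype=np.float64)

        ei, ev = read(entity_path)
        ri, rv = read(relation_path)
        return cls(ei, ri, ev, rv)


def score_triplet(h: np.ndarray, r: np.ndarray, t: np.ndarray,
                  norm: str = "L2") -> float:
    """Negative translation distance ``-‖h + r - t‖``; 0 iff h + r = t."""
    h, r, t = np.asarray(h), np.asarray(r), np.asarray(t)
    if not (h.shape == r.shape == t.shape):
        raise ValueError(f"dimension mismatch: {h.shape}, {r.shape}, {t.shape}")
    diff = h + r - t
    if norm == "L1":
        return float(-np.abs(diff).sum())
    if norm == "L2":
        return float(-np.sqrt((diff * diff).sum()))
    raise ValueError("norm must be 'L1' or 'L2'")


def margin_loss(pos_score: float, neg_score: float, margin: float) -> float:
    """Per-pair hinge term ``max(0, γ - f(pos) + f(neg))``."""
    return max(0.0, margin - pos_score + neg_score)


def corrupt_triplet(triplet: KGTriplet, entity_pool: list[str],
                    positive_set: set[tuple[str, str, str]],
                    rng: np.random.Generator,
                    max_retries: int = 100) -> KGTriplet:
    """Draw a negative by replacing the head or tail (side chosen 50/50)
    with a uniform entity so that the result is not a positive triplet."""
    if not entity_pool:
        raise SamplingError("empty entity pool")
    for _ in range(max_retries):
        side_head = rng.random() < 0.5
        repl = entity_pool[int(rng.integers(len(entity_pool)))]
        if side_head:
            cand = (repl, triplet.relation, triplet.tail)
        else:
            cand = (triplet.head, triplet.relation, repl)
        if cand not in positive_set and cand != (triplet.head, triplet.relation, triplet.tail):
            return KGTriplet(*cand)
    raise SamplingError(
        f"no valid corruption found for {triplet} after {max_retries} retries"
    )


def _vectorized_corrupt(heads, tails, rels, n_entities, positive_set, rng,
                        max_retries: int = 100):
    """Batch corruption used inside the trainer (same semantics as
    :func:`corrupt_triplet`, integer-indexed)."""
    n = len(heads)
    ch, ct = heads.copy(), tails.copy()
    side_head = rng.random(n) < 0.5
    pending = np.arange(n)
    for _ in range(max_retries):
        repl = rng.integers(n_entities, size=len(pending))
        ch[pending] = np.where(side_head[pending], repl, ch[pending])
        ct[pending] = np.where(side_head[pending], ct[pending], repl)
        bad = [
            k
            for k in pending
            if (ch[k], rels[k], ct[k]) in positive_set
        ]
        if not bad:
            return ch, ct
        pending = np.asarray(bad)
        ch[pending] = heads[pending]
        ct[pending] = tails[pending]
    raise SamplingError("corruption retries exhausted during training")


def train_transe(triplets: list[KGTriplet],
                 cfg: TransEConfig) -> tuple[KGEmbeddingTable, list[float]]:
    """Minibatch SGD on the margin ranking loss; returns the table and the
    per-epoch mean loss trace.  Deterministic given ``cfg.seed``."""
    if len(triplets) < 1:
        raise ValueError("need at least one triplet")
    entities = sorted({t.head for t in triplets} | {t.tail for t in triplets})
    relations = sorted({t.relation for t in triplets})
    if len(entities) < 2:
        raise ValueError("need at least two entities")
    e_index = {e: i for i, e in enumerate(entities)}
    r_index = {r: i for i, r in enumerate(relations)}
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dim_kge
    bound = 6.0 / np.sqrt(d)
    E = rng.uniform(-bound, bound, size=(len(entities), d))
    R = rng.uniform(-bound, bound, size=(len(relations), d))
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)

    heads = np.array([e_index[t.head] for t in triplets])
    rels = np.array([r_index[t.relation] for t in triplets])
    tails = np.array([e_index[t.tail] for t in triplets])
    positive = {(e_index[t.head], r_index[t.relation], e_index[t.tail])
                for t in triplets}
    n = len(triplets)
    l1 = cfg.norm == "L1"
    trace: list[float] = []
    for _ in range(cfg.epochs):
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            bh, br, bt = heads[idx], rels[idx], tails[idx]
            for _neg in range(cfg.negatives_per_positive):
                nh, nt = _vectorized_corrupt(bh, bt, br, len(entities),
                                             positive, rng)
                dp = E[bh] + R[br] - E[bt]
                dn = E[nh] + R[br] - E[nt]
                if l1:
                    pd = np.abs(dp).sum(axis=1)
                    nd = np.abs(dn).sum(axis=1)
                    gp, gn = np.sign(dp), np.sign(dn)
                else:
                    pd = np.linalg.norm(dp, axis=1)
                    nd = np.linalg.norm(dn, axis=1)
                    gp = dp / np.maximum(pd, 1e-12)[:, None]
                    gn = dn / np.maximum(nd, 1e-12)[:, None]
                viol = cfg.margin + pd - nd  # = γ - f(pos) + f(neg)
                active = viol > 0
                epoch_loss += float(viol[active].sum())
                if not active.any():
                    continue
                lr = cfg.lr
                gpa = lr * gp[active]
                gna = lr * gn[active]
                np.add.at(E, bh[active], -gpa)
                np.add.at(E, bt[active], gpa)
                np.add.at(R, br[active], -gpa)
                np.add.at(E, nh[active], gna)
                np.add.at(E, nt[active], -gna)
                np.add.at(R, br[active], gna)
        trace.append(epoch_loss / (n * cfg.negatives_per_positive))
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
    table = KGEmbeddingTable(e_index, r_index, E, R)
    return table, trace


def extract_drug_kge(table: KGEmbeddingTable, drug_ids: list[str]) -> np.ndarray:
    """Per-drug embedding matrix; drugs absent from the KG get the zero
    vector (with a warning), mirroring the dataset-assembly fallback."""
    out = np.zeros((len(drug_ids), table.dim))
    for i, did in enumerate(drug_ids):
        if did in table.entity_index:
            out[i] = table.entity(did)
        else:
            warnings.warn(
                f"drug {did!r} absent from KG; using zero network embedding",
                stacklevel=2,
            )
    return out


def mean_tail_rank(table: KGEmbeddingTable, triplets: list[KGTriplet],
                   norm: str = "L2") -> float:
    """Mean rank (1-based) of the true tail among all entities by score,
    averaged over the given triplets.  Random vectors give about
    ``(n_entities + 1) / 2``."""
    E, R = table.entity_vectors, table.relation_vectors
    ranks = []
    for t in triplets:
        h = E[table.entity_index[t.head]]
        r = R[table.relation_index[t.relation]]
        target = h + r
        diff = E - target[None, :]
        if norm == "L1":
            dist = np.abs(diff).sum(axis=1)
        else:
            dist = np.linalg.norm(diff, axis=1)
        true_idx = table.entity_index[t.tail]
        rank = 1 + int((dist < dist[true_idx]).sum())
        ranks.append(rank)
    return float(np.mean(ranks))
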