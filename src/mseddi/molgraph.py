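"""Molecular graphs and chemical-structure embeddings.

SMILES strings are parsed with RDKit into attributed, undirected
heavy-atom graphs: eight atom attribute groups (element one-hot, degree,
formal charge, chirality tag, attached-H count, hybridization,
aromaticity, scaled mass) and four bond attribute groups (bond type,
conjugation, ring membership, stereo).  Three message-passing encoders
share the same synchronous aggregation/update scheme built from linear
maps and differ in their permutation-invariant readout:

* ``mpnn`` — a recurrent attention pooling in the Set2Set spirit (a query
  vector repeatedly attends over node states and is updated from the
  attended sum; no LSTM cell),
* ``weave`` — node-state sum followed by a linear tail,
* ``afp``  — three stacked gated-attention global pooling layers.

The encoders are differentiable end-to-end and are trained jointly with
the pair model (a frozen mode is available through the training layer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from ._tensor import Module, Tensor, concat
from .nn import Linear

RDLogger.DisableLog("rdApp.*")  # parse errors are raised, not printed

__all__ = [
    "MolGraph",
    "MolBatch",
    "GraphEncoderConfig",
    "MolParseError",
    "smiles_to_molgraph",
    "message_pass",
    "GraphEncoder",
    "encode_molecule",
    "batch_graphs",
    "VARIANTS",
]

VARIANTS = ("mpnn", "weave", "afp")

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + other slot
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_CHIRAL = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
]

ATOM_FEATURES = len(_ELEMENTS) + 1 + 7 + 1 + len(_CHIRAL) + 1 + 6 + len(_HYBRID) + 1 + 1 + 1
BOND_FEATURES = (len(_BOND_TYPES) + 1) + 1 + 1 + (len(_STEREO) + 1)


class MolParseError(ValueError):
    """SMILES string rejected by the chemistry parser."""


@dataclass
class MolGraph:
    """Attributed undirected molecular graph (heavy atoms only)."""

    atom_features: np.ndarray            # (n_atoms, ATOM_FEATURES)
    bonds: list[tuple[int, int, np.ndarray]]  # (u, v, bond feature vector)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self) -> list[list[tuple[int, np.ndarray]]]:
        adj: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(self.n_atoms)]
        for u, v, e in self.bonds:
            adj[u].append((v, e))
            adj[v].append((u, e))
        return adj

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for u, v, _ in self.bonds:
            a[u, v] = a[v, u] = 1.0
        return a


def _one_hot(value, choices: list, other_slot: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if other_slot:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4, 5], other_slot=True)
        + [float(atom.GetFormalCharge())]
        + _one_hot(atom.GetChiralTag(), _CHIRAL)
        + _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3, 4], other_slot=True)
        + _one_hot(atom.GetHybridization(), _HYBRID)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    return np.asarray(feats)


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(bond.GetStereo(), _STEREO)
    )
    return np.asarray(feats)


def smiles_to_molgraph(s: str) -> MolGraph:
    """Parse a SMILES string into a featurized heavy-atom graph."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise MolParseError(f"unparsable SMILES: {s!r}")
    atoms = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_features(b))
        for b in mol.GetBonds()
    ]
    return MolGraph(atoms, bonds)


def message_pass(graph: MolGraph, state, aggregate, update):
    """One synchronous message-passing round.

    ``aggregate(h_x, h_y, e_xy)`` is summed over the neighbors of each
    node (zero for isolated nodes) and ``update(h_x, a_x)`` produces the
    new state; all nodes update simultaneously from the old states.
    """
    neigh = graph.neighbors()
    new_states = []
    for x in range(graph.n_atoms):
        msgs = [aggregate(state[x], state[y], e) for y, e in neigh[x]]
        a = np.sum(msgs, axis=0) if msgs else np.zeros_like(np.asarray(state[x], dtype=float))
        new_states.append(update(state[x], a))
    return np.asarray(new_states)


@dataclass
class GraphEncoderConfig:
    variant: str = "mpnn"
    dim_cse: int = 32
    rounds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.rounds < 1 or self.dim_cse < 1:
            raise ValueError("rounds and dim_cse must be >= 1")


@dataclass
class MolBatch:
    """Dense padded batch of molecular graphs.

    ``edge_sums[b, x]`` holds the sum of incident bond feature vectors of
    atom x — with linear aggregation maps this is all the edge information
    a message-passing round needs.
    """

    atom: np.ndarray       # (n_mols, max_atoms, ATOM_FEATURES)
    adjacency: np.ndarray  # (n_mols, max_atoms, max_atoms)
    edge_sums: np.ndarray  # (n_mols, max_atoms, BOND_FEATURES)
    mask: np.ndarray       # (n_mols, max_atoms, 1), 1.0 for real atoms

    def subset(self, indices: np.ndarray) -> "MolBatch":
        return MolBatch(self.atom[indices], self.adjacency[indices],
                        self.edge_sums[indices], self.mask[indices])


def batch_graphs(graphs: list[MolGraph], dtype=np.float32) -> MolBatch:
    if any(g.n_atoms == 0 for g in graphs):
        raise ValueError("cannot batch an empty molecular graph")
    n = len(graphs)
    max_atoms = max(g.n_atoms for g in graphs)
    atom = np.zeros((n, max_atoms, ATOM_FEATURES), dtype=dtype)
    adj = np.zeros((n, max_atoms, max_atoms), dtype=dtype)
    edges = np.zeros((n, max_atoms, BOND_FEATURES), dtype=dtype)
    mask = np.zeros((n, max_atoms, 1), dtype=dtype)
    for i, g in enumerate(graphs):
        atom[i, : g.n_atoms] = g.atom_features
        adj[i, : g.n_atoms, : g.n_atoms] = g.adjacency()
        for u, v, e in g.bonds:
            edges[i, u] += e
            edges[i, v] += e
        mask[i, : g.n_atoms] = 1.0
    return MolBatch(atom, adj, edges, mask)


def _masked_softmax(logits: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    neg = (1.0 - mask) * np.asarray(-1e9, dtype=logits.data.dtype)
    return (logits + neg).softmax(axis=axis)


class GraphEncoder(Module):
    """Message passing plus a variant-specific readout; maps a batch of
    molecular graphs to ``(n_mols, dim_cse)`` embeddings."""

    def __init__(self, cfg: GraphEncoderConfig, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        d = cfg.dim_cse
        self.cfg = cfg
        self.proj = Linear(ATOM_FEATURES, d, rng, dtype=dtype)
        # aggregation A(h_x, h_y, e_xy) = W_a h_y + W_e e_xy, summed over
        # neighbors; update U(h, a) = LeakyReLU(W_h h + W_u a + b)
        self.W_a = Linear(d, d, rng, bias=False, dtype=dtype)
        self.W_e = Linear(BOND_FEATURES, d, rng, bias=False, dtype=dtype)
        self.W_h = Linear(d, d, rng, dtype=dtype)
        self.W_u = Linear(d, d, rng, bias=False, dtype=dtype)
        if cfg.variant == "weave":
            self.tail = Linear(d, d, rng, dtype=dtype)
        elif cfg.variant == "mpnn":
            self.query_update = Linear(2 * d, d, rng, dtype=dtype)
            self.tail = Linear(2 * d, d, rng, dtype=dtype)
        else:  # afp
            self.att = [Linear(2 * d, 1, rng, dtype=dtype) for _ in range(3)]
            self.val = [Linear(d, d, rng, bias=False, dtype=dtype) for _ in range(3)]
            self.upd = [Linear(d, d, rng, bias=False, dtype=dtype) for _ in range(3)]
            self.tail = Linear(d, d, rng, dtype=dtype)

    # -- phases ---------------------------------------------------------
    def _propagate(self, batch: MolBatch) -> Tensor:
        mask = batch.mask
        h = (self.proj(Tensor(batch.atom))) * mask
        edge_term = self.W_e(Tensor(batch.edge_sums))
        adj = Tensor(batch.adjacency)
        for _ in range(self.cfg.rounds):
            agg = adj @ self.W_a(h) + edge_term
            h = (self.W_h(h) + self.W_u(agg)).leaky_relu() * mask
        return h

    def _readout(self, h: Tensor, mask: np.ndarray) -> Tensor:
        b, n, d = h.shape
        if self.cfg.variant == "weave":
            return self.tail(h.sum(axis=1))
        if self.cfg.variant == "mpnn":
            q = Tensor(np.zeros((b, d), dtype=h.data.dtype))
            read = Tensor(np.zeros((b, d), dtype=h.data.dtype))
            for _ in range(3):
                logits = h @ q.reshape(b, d, 1)            # (b, n, 1)
                attn = _masked_softmax(logits, mask, axis=1)
                read = (attn * h).sum(axis=1)              # (b, d)
                q = self.query_update(concat([q, read], axis=1)).tanh()
            return self.tail(concat([q, read], axis=1))
        # afp: gated attention pooling, graph state seeded by the mean node
        counts = mask.sum(axis=1)
        s = h.sum(axis=1) * (1.0 / counts)
        for att, val, upd in zip(self.att, self.val, self.upd):
            ones = np.ones((1, n, 1), dtype=h.data.dtype)
            s_rows = s.reshape(b, 1, d) * ones
            logits = att(concat([s_rows, h], axis=2)).leaky_relu()
            attn = _masked_softmax(logits, mask, axis=1)
            context = (attn * val(h)).sum(axis=1)
            s = (context + upd(s)).leaky_relu()
        return self.tail(s)

    def forward(self, batch: MolBatch) -> Tensor:
        if batch.atom.shape[1] == 0:
            raise ValueError("readout of an empty graph is undefined")
        return self._readout(self._propagate(batch), batch.mask)

    __call__ = forward


def encode_molecule(graph: MolGraph, encoder: GraphEncoder) -> np.ndarray:
    """Embed a single molecule (convenience wrapper over a 1-graph batch)."""
    dtype = encoder.proj.W.data.dtype
    out = encoder(batch_graphs([graph], dtype=dtype))
    return out.data[0]
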