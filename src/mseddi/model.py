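"""Three-channel drug-pair model with self-attention fusion.

Every drug arrives with three representations: a knowledge-graph vector
(network channel), a 100-row SMILES notation embedding (sequence channel)
and three molecular-graph embeddings (graph channel).  Each channel
re-learns its inputs into a fixed number of ``dim``-wide rows per pair —
2 for the network channel, 50 for the sequence channel (two spliced
100-row embeddings convolved and max-pooled by 4), and 6 for the graph
channel (three encoder variants × two drugs).  The stacked 58-row pair
representation is fused by multi-head self-attention, flattened, and
mapped to event logits by an MLP predictor.

Ablation variants are plain configuration: ``channel_mask`` keeps a
subset of channels (NC/SC/GC), ``use_residual`` removes the sequence
channel's residual connection (NO_ADD), ``use_graph_conv`` removes the
graph-channel convolution (NO_CONV) and ``use_fusion_attention`` replaces
fused attention by plain concatenation (NO_ATTEN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Module, Tensor, concat
from .molgraph import GraphEncoder, GraphEncoderConfig, MolBatch, VARIANTS
from .nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    Linear,
    LayerNorm,
    MLPBlock,
    MultiHeadSelfAttention,
)

__all__ = ["ModelConfig", "DrugFeatures", "MSEDDIModel", "CHANNELS"]

CHANNELS = ("network", "sequence", "graph")
_CHANNEL_ROWS = {"network": 2, "sequence": 50, "graph": 6}


@dataclass
class ModelConfig:
    dim: int = 32
    dropout: float = 0.2
    attn_heads: int = 4
    n_events: int = 8
    dim_kge: int = 32
    dim_sne: int = 32
    dim_cse: int = 32
    gnn_rounds: int = 3
    channel_mask: tuple[str, ...] = CHANNELS
    use_residual: bool = True
    use_fusion_attention: bool = True
    use_graph_conv: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        mask = tuple(self.channel_mask)
        if not mask or any(c not in CHANNELS for c in mask):
            raise ValueError(f"channel_mask must be a nonempty subset of {CHANNELS}")
        self.channel_mask = tuple(c for c in CHANNELS if c in mask)

    @property
    def n_rows(self) -> int:
        return sum(_CHANNEL_ROWS[c] for c in self.channel_mask)


@dataclass
class DrugFeatures:
    """Frozen per-drug inputs, indexed by bundle drug position."""

    kge: np.ndarray        # (n_drugs, dim_kge)
    sne: np.ndarray        # (n_drugs, 100, dim_sne)
    graphs: MolBatch       # batched molecular graphs, same order

    @property
    def n_drugs(self) -> int:
        return self.kge.shape[0]


class MSEDDIModel(Module):
    """The full three-channel pair model (see module docstring)."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        d = cfg.dim
        # network channel: one MLP shared by both drugs of the pair
        self.kge_mlp = MLPBlock(cfg.dim_kge, d, d, rng, dtype=dtype)
        # sequence channel
        self.seq_conv = Conv1d(cfg.dim_sne, d, 3, rng, dtype=dtype)
        self.seq_bn = BatchNorm1d(d, dtype=dtype)
        self.seq_attn = MultiHeadSelfAttention(d, cfg.attn_heads, rng,
                                               dropout=cfg.dropout, dtype=dtype)
        self.seq_ln1 = LayerNorm(d, dtype=dtype)
        self.seq_ff1 = Linear(d, 2 * d, rng, dtype=dtype)
        self.seq_ff2 = Linear(2 * d, d, rng, dtype=dtype)
        self.seq_ln2 = LayerNorm(d, dtype=dtype)
        # graph channel: three jointly trained encoders + three separate MLPs
        self.encoders = {
            v: GraphEncoder(
                GraphEncoderConfig(variant=v, dim_cse=cfg.dim_cse,
                                   rounds=cfg.gnn_rounds,
                                   seed=cfg.seed + 101 + i),
                dtype=dtype,
            )
            for i, v in enumerate(VARIANTS)
        }
        self.cse_mlps = {v: MLPBlock(cfg.dim_cse, d, d, rng, dtype=dtype)
                         for v in VARIANTS}
        self.cse_conv = Conv1d(d, d, 3, rng, dtype=dtype)
        self.cse_bn = BatchNorm1d(d, dtype=dtype)
        # fusion + predictor
        self.fusion_attn = MultiHeadSelfAttention(d, cfg.attn_heads, rng,
                                                  dropout=cfg.dropout, dtype=dtype)
        self.fusion_ln = LayerNorm(d, dtype=dtype)
        self.predictor = MLPBlock(cfg.n_rows * d, d, cfg.n_events, rng, dtype=dtype)
        self.channel_drop = {c: Dropout(cfg.dropout, rng) for c in CHANNELS}
        # drug indices seen by forward passes (cold-start audit trail)
        self.accessed_drugs: set[int] = set()

    # -- channels --------------------------------------------------------
    def network_channel(self, h_i: Tensor | np.ndarray,
                        h_j: Tensor | np.ndarray) -> Tensor:
        """(B, dim_kge) × 2 → (B, 2, dim): shared MLP, drug-i row first."""
        h_i = h_i if isinstance(h_i, Tensor) else Tensor(h_i.astype(self.dtype))
        h_j = h_j if isinstance(h_j, Tensor) else Tensor(h_j.astype(self.dtype))
        b = h_i.shape[0]
        both = self.kge_mlp(concat([h_i, h_j], axis=0))
        d = both.shape[-1]
        out = concat(
            [both.narrow(0, 0, b).reshape(b, 1, d),
             both.narrow(0, b, b).reshape(b, 1, d)],
            axis=1,
        )
        return self.channel_drop["network"](out)

    def sequence_channel(self, s_i: np.ndarray, s_j: np.ndarray) -> Tensor:
        """Two (B, 100, dim_sne) notation embeddings → (B, 50, dim)."""
        if s_i.shape[1] != 100 or s_j.shape[1] != 100:
            raise ValueError("sequence embeddings must have exactly 100 rows")
        x = Tensor(np.concatenate([s_i, s_j], axis=1).astype(self.dtype))
        z = self.seq_bn(self.seq_conv(x))                     # (B, 200, dim)
        b, length, d = z.shape
        z = z.reshape(b, length // 4, 4, d).max(axis=2)       # max-pool k4 s4
        s1 = z.leaky_relu()                                   # (B, 50, dim)
        s2 = self.seq_ln1(self.seq_attn(s1))
        ff = self.seq_ln2(self.seq_ff2(self.seq_ff1(s2).gelu()))
        out = s1 + ff if self.cfg.use_residual else ff
        return self.channel_drop["sequence"](out)

    def graph_channel(self, pair_embeddings: dict[str, tuple[Tensor, Tensor]]
                      ) -> Tensor:
        """Per-variant (drug-i, drug-j) structure embeddings → (B, 6, dim)."""
        for v in VARIANTS:
            if v not in pair_embeddings:
                raise ValueError(f"missing structure embedding for variant {v!r}")
        rows = []
        b = None
        for v in VARIANTS:
            e_i, e_j = pair_embeddings[v]
            e_i = e_i if isinstance(e_i, Tensor) else Tensor(np.asarray(e_i, dtype=self.dtype))
            e_j = e_j if isinstance(e_j, Tensor) else Tensor(np.asarray(e_j, dtype=self.dtype))
            b = e_i.shape[0]
            both = self.cse_mlps[v](concat([e_i, e_j], axis=0))
            d = both.shape[-1]
            rows.append(both.narrow(0, 0, b).reshape(b, 1, d))
            rows.append(both.narrow(0, b, b).reshape(b, 1, d))
        stack = concat(rows, axis=1)                          # (B, 6, dim)
        if self.cfg.use_graph_conv:
            out = self.cse_bn(self.cse_conv(stack)).leaky_relu()
        else:
            out = stack.leaky_relu()
        return self.channel_drop["graph"](out)

    # -- fusion ----------------------------------------------------------
    def fuse_and_predict(self, channel_outputs: list[Tensor]) -> Tensor:
        """Stack channel rows, fuse by self-attention, flatten, predict
        event logits."""
        if not channel_outputs:
            raise ValueError("no channel enabled")
        p = concat(channel_outputs, axis=1)
        if self.cfg.use_fusion_attention:
            p = self.fusion_ln(self.fusion_attn(p))
        b, rows, d = p.shape
        return self.predictor(p.reshape(b, rows * d))

    # -- full forward ----------------------------------------------------
    def forward_logits(self, i_idx: np.ndarray, j_idx: np.ndarray,
                       features: DrugFeatures) -> Tensor:
        i_idx = np.asarray(i_idx, dtype=int)
        j_idx = np.asarray(j_idx, dtype=int)
        self.accessed_drugs.update(int(k) for k in i_idx)
        self.accessed_drugs.update(int(k) for k in j_idx)
        outputs = []
        if "network" in self.cfg.channel_mask:
            outputs.append(
                self.network_channel(features.kge[i_idx], features.kge[j_idx])
            )
        if "sequence" in self.cfg.channel_mask:
            outputs.append(
                self.sequence_channel(features.sne[i_idx], features.sne[j_idx])
            )
        if "graph" in self.cfg.channel_mask:
            # encode each distinct drug in the batch once; pairs gather rows
            uniq, inv = np.unique(np.concatenate([i_idx, j_idx]), return_inverse=True)
            sub = features.graphs.subset(uniq)
            n = len(i_idx)
            pair_embeddings = {}
            for v in VARIANTS:
                emb = self.encoders[v](sub)                  # (U, dim_cse)
                pair_embeddings[v] = (
                    emb.gather_rows(inv[:n]),
                    emb.gather_rows(inv[n:]),
                )
            outputs.append(self.graph_channel(pair_embeddings))
        return self.fuse_and_predict(outputs)

    def predict_proba(self, i_idx, j_idx, features: DrugFeatures,
                      batch_size: int = 256) -> np.ndarray:
        """Eval-mode class probabilities, computed in chunks."""
        was_training = self.training
        self.eval()
        i_idx = np.asarray(i_idx, dtype=int)
        j_idx = np.asarray(j_idx, dtype=int)
        chunks = []
        for start in range(0, len(i_idx), batch_size):
            sl = slice(start, start + batch_size)
            logits = self.forward_logits(i_idx[sl], j_idx[sl], features)
            chunks.append(logits.softmax(axis=-1).data)
        if was_training:
            self.train()
        return np.concatenate(chunks, axis=0)
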