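"""SMILES notation embedding: tokenizer, CBOW trainer, fold/pad rule.

Each drug's SMILES string is tokenized (character-level, with the
two-character organic-subset halogens ``Cl``/``Br`` and bracket atoms
``[...]`` kept whole), a continuous-bag-of-words embedder is trained with
a full softmax over the token vocabulary, and per-drug sequences are
embedded by look-up into the input weight matrix ``W1``.  Sequences are
brought to a fixed 100-row shape: shorter ones are zero-padded, longer
ones are folded into consecutive 100-row chunks and averaged with a mask
so padding never dilutes real rows.  The embedder is pretrained on the
corpus of all drug SMILES and frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "W2VConfig",
    "TokenVocabulary",
    "TokenizationError",
    "tokenize_smiles",
    "cbow_forward",
    "train_cbow",
    "embed_sequence",
    "fold_and_pad",
    "notation_embeddings",
]

MAX_LEN = 100  # fixed row count of every sequence embedding


class TokenizationError(ValueError):
    """Malformed SMILES at the token level (e.g. unbalanced brackets)."""


@dataclass
class W2VConfig:
    dim_sne: int = 32
    window: int = 5
    lr: float = 0.025
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.dim_sne < 1 or self.window < 1 or self.epochs < 0:
            raise ValueError("invalid CBOW configuration")


@dataclass
class TokenVocabulary:
    tokens: list[str]

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int | None:
        return self._index.get(token)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(s: str) -> list[str]:
    """Character tokens, with ``Cl``, ``Br`` and bracket atoms ``[...]``
    emitted whole."""
    if not s:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c == "[":
            j = s.find("]", i + 1)
            if j < 0:
                raise TokenizationError(f"unbalanced '[' in {s!r}")
            tokens.append(s[i:j + 1])
            i = j + 1
        elif c == "]":
            raise TokenizationError(f"unbalanced ']' in {s!r}")
        elif s[i:i + 2] in ("Cl", "Br"):
            tokens.append(s[i:i + 2])
            i += 2
        else:
            tokens.append(c)
            i += 1
    return tokens


def cbow_forward(context_indices, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Softmax(mean of context rows of W1 · W2); a probability vector."""
    context_indices = np.asarray(context_indices, dtype=int)
    if context_indices.size == 0:
        raise ValueError("empty context")
    m = W1[context_indices].mean(axis=0)
    logits = m @ W2
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _context(tokens_idx: np.ndarray, j: int, window: int) -> np.ndarray:
    """Window truncated at sequence boundaries (no padding tokens)."""
    lo = max(0, j - window)
    hi = min(len(tokens_idx), j + window + 1)
    return np.concatenate([tokens_idx[lo:j], tokens_idx[j + 1:hi]])


def train_cbow(corpus: list[list[str]],
               cfg: W2VConfig) -> tuple[np.ndarray, TokenVocabulary]:
    """Full-softmax CBOW by SGD on the summed cross-entropy.

    Returns the input embedding matrix ``W1`` (v × dim_sne) and the token
    vocabulary (tokens in first-appearance order).  Deterministic given
    ``cfg.seed``: fixed iteration order, seeded initialization.
    """
    if not corpus:
        raise ValueError("empty corpus")
    tokens: list[str] = []
    seen: set[str] = set()
    for seq in corpus:
        for t in seq:
            if t not in seen:
                seen.add(t)
                tokens.append(t)
    vocab = TokenVocabulary(tokens)
    v, u = vocab.size, cfg.dim_sne
    rng = np.random.default_rng(cfg.seed)
    W1 = rng.uniform(-0.5 / u, 0.5 / u, size=(v, u))
    W2 = rng.uniform(-0.5 / u, 0.5 / u, size=(u, v))
    seqs = [np.array([vocab.index(t) for t in seq], dtype=int) for seq in corpus]
    for _ in range(cfg.epochs):
        for seq in seqs:
            if len(seq) < 2:
                continue  # no context pairs, no update
            for j in range(len(seq)):
                ctx = _context(seq, j, cfg.window)
                m = W1[ctx].mean(axis=0)
                logits = m @ W2
                z = logits - logits.max()
                e = np.exp(z)
                p = e / e.sum()
                p[seq[j]] -= 1.0  # d(CE)/d(logits)
                gW2 = np.outer(m, p)
                gm = W2 @ p
                W2 -= cfg.lr * gW2
                np.add.at(W1, ctx, -cfg.lr * gm / len(ctx))
    return W1, vocab


def embed_sequence(tokens: list[str], W1: np.ndarray,
                   vocab: TokenVocabulary) -> np.ndarray:
    """Row j is W1's row for token j (the one-hot product identity);
    out-of-vocabulary tokens give a zero row and a warning."""
    u = W1.shape[1]
    out = np.zeros((len(tokens), u), dtype=W1.dtype)
    for j, tok in enumerate(tokens):
        idx = vocab.index(tok)
        if idx is None:
            warnings.warn(f"token {tok!r} not in vocabulary; zero row", stacklevel=2)
        else:
            out[j] = W1[idx]
    return out


def fold_and_pad(mat: np.ndarray, max_len: int = MAX_LEN) -> np.ndarray:
    """Bring a ``len × u`` sequence embedding to ``max_len × u``.

    Short sequences are zero-padded.  Longer ones are split into
    consecutive ``max_len``-row chunks and averaged position-wise over the
    chunks that actually hold a row at that offset (a mask-aware mean:
    the short final chunk never drags positions toward zero).
    """
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D sequence embedding")
    length, u = mat.shape
    out = np.zeros((max_len, u), dtype=mat.dtype)
    if length == 0:
        return out
    if length <= max_len:
        out[:length] = mat
        return out
    counts = np.zeros(max_len, dtype=int)
    for start in range(0, length, max_len):
        chunk = mat[start:start + max_len]
        out[: len(chunk)] += chunk
        counts[: len(chunk)] += 1
    out /= np.maximum(counts, 1)[:, None]
    return out


def notation_embeddings(smiles_list: list[str], cfg: W2VConfig
                        ) -> tuple[np.ndarray, np.ndarray, TokenVocabulary]:
    """Pretrain CBOW on all drug SMILES and emit the stacked per-drug
    ``(n_drugs, 100, dim_sne)`` sequence embeddings, plus W1 and vocab."""
    corpus = [tokenize_smiles(s) for s in smiles_list]
    W1, vocab = train_cbow(corpus, cfg)
    H = np.stack([
        fold_and_pad(embed_sequence(toks, W1, vocab)) for toks in corpus
    ])
    return H, W1, vocab
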