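"""Skip-gram token embeddings for molecular string symbols.

Each drug is a "sentence" of SELFIES (or SMILES) tokens; a small word2vec
style skip-gram model with a full softmax objective embeds every token, and
a drug vector is the mean of its token vectors. Each epoch is one
mini-batch SGD pass over all (center, context) pairs in a seeded shuffle
order, so training is exactly reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DrugRecord


@dataclass
class EmbeddingParams:
    dim: int = 64
    window: int = 5
    epochs: int = 100
    lr: float = 0.1
    batch_size: int = 1024
    seed: int = 0


@dataclass
class TokenEmbeddingTable:
    """Learned vectors for a token vocabulary."""

    vocabulary: list[str]
    vectors: np.ndarray  # (|vocab|, dim)
    params: EmbeddingParams = field(default_factory=EmbeddingParams)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]


def _skipgram_pairs(corpus: list[list[str]], index: dict[str, int], window: int):
    centers, contexts = [], []
    for sent in corpus:
        ids = [index[t] for t in sent]
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            hi = min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    return np.asarray(centers, dtype=np.intp), np.asarray(contexts, dtype=np.intp)


def train_token_embeddings(
    corpus: list[list[str]], params: EmbeddingParams | None = None
) -> TokenEmbeddingTable:
    """Train skip-gram embeddings over a corpus of token sentences.

    The objective is the cross-entropy of predicting each context token
    from its center token through a softmax over the vocabulary. Every
    epoch shuffles all pairs with the seeded generator and performs
    mini-batch SGD over them, so retraining with the same corpus, params
    and seed yields identical vectors.
    """
    if params is None:
        params = EmbeddingParams()
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("empty corpus")
    vocab = sorted({t for sent in corpus for t in sent})
    index = {t: i for i, t in enumerate(vocab)}
    centers, contexts = _skipgram_pairs(corpus, index, params.window)
    rng = np.random.default_rng(params.seed)
    v, d = len(vocab), params.dim
    w_in = rng.standard_normal((v, d)) * 0.1
    w_out = rng.standard_normal((v, d)) * 0.1
    if centers.size == 0:
        # single-token sentences: no context pairs, keep the random init
        return TokenEmbeddingTable(vocab, w_in, params)
    n = centers.size
    bs = max(1, min(params.batch_size, n))
    for _ in range(params.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            c, t = centers[sel], contexts[sel]
            x = w_in[c]                            # (b, d)
            logits = x @ w_out.T                   # (b, v)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(sel.size), t] -= 1.0       # dL/dlogits (mean loss)
            p /= sel.size
            g_in = p @ w_out                       # (b, d)
            g_w_out = p.T @ x                      # (v, d)
            w_out -= params.lr * g_w_out
            g_w_in = np.zeros_like(w_in)
            np.add.at(g_w_in, c, g_in)
            w_in -= params.lr * g_w_in
    return TokenEmbeddingTable(vocab, w_in, params)


def embed_drug(record: DrugRecord, table: TokenEmbeddingTable) -> np.ndarray:
    """Mean-pool a drug's token vectors into one representation vector.

    Tokens missing from the vocabulary are dropped; a drug whose tokens are
    all unknown has no representation and raises.
    """
    if not record.tokens:
        raise ValueError(f"drug {record.drug_id} has no tokens")
    vecs = [table.vector(t) for t in record.tokens if t in table]
    if not vecs:
        raise ValueError(f"drug {record.drug_id}: all tokens unknown to the embedding table")
    return np.mean(vecs, axis=0)
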