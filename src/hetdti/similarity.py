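"""Drug and protein similarity matrices.

Proteins: all-pairs Smith-Waterman scores, row-wise min-max normalized

    S_P(i,j) = (SW(i,j) - min SW_i) / (max SW_i - min SW_i)

with the row min/max taken over the full row including the diagonal, so a
protein's self-similarity maps to exactly 1. The row-wise normalization is
asymmetric; the result is symmetrized by averaging with its transpose and
the diagonal is reset to 1.

Drugs: each drug's SELFIES (or SMILES) token sequence is embedded by the
skip-gram model, token vectors are mean-pooled into one vector per drug,
and S_D is the pairwise cosine similarity clipped into [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AlignmentScoring, pairwise_sw_scores
from .embeddings import EmbeddingParams, TokenEmbeddingTable, embed_drug, train_token_embeddings
from .io_formats import DrugRecord, ProteinRecord, MAX_DRUG_TOKENS
from .selfies_codec import encode_selfies, tokenize_selfies, tokenize_smiles

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """A symmetric entity-by-entity similarity matrix with values in [0, 1]."""

    ids: list[str]
    values: np.ndarray
    entity_kind: str  # "drug" or "protein"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape must match the id list")
        self.values = v
        self._index = {e: i for i, e in enumerate(self.ids)}

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for eid, row in zip(self.ids, self.values):
                fh.write(eid + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, entity_kind: str) -> "SimilarityMatrix":
        with open(path, encoding="utf-8") as fh:
            ids = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(ids=ids, values=np.asarray(rows), entity_kind=entity_kind)


def row_minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Normalize each row of a raw score matrix to [0, 1] by its min and max.

    The min/max run over the whole row including the diagonal. A degenerate
    row (max == min) becomes 0 off-diagonal and 1 on the diagonal, with a
    warning.
    """
    raw = np.asarray(raw, dtype=np.float64)
    out = np.empty_like(raw)
    for i, row in enumerate(raw):
        lo, hi = row.min(), row.max()
        if hi == lo:
            warnings.warn(f"degenerate similarity row {i}: all scores equal", stacklevel=2)
            out[i] = 0.0
            out[i, i] = 1.0
        else:
            out[i] = (row - lo) / (hi - lo)
    return out


def _symmetrize_unit_diag(m: np.ndarray) -> np.ndarray:
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return np.clip(m, 0.0, 1.0)


def protein_similarity_matrix(
    proteins: list[ProteinRecord], scoring: AlignmentScoring | None = None
) -> SimilarityMatrix:
    """Smith-Waterman similarity matrix S_P over a protein list."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    if scoring is None:
        scoring = AlignmentScoring.blosum62()
    raw = pairwise_sw_scores([p.sequence for p in proteins], scoring)
    values = _symmetrize_unit_diag(row_minmax_normalize(raw))
    return SimilarityMatrix(ids=[p.protein_id for p in proteins], values=values,
                            entity_kind="protein")


def prepare_drugs(
    records: list[DrugRecord],
    encoding: str = "selfies",
    max_tokens: int = MAX_DRUG_TOKENS,
) -> list[DrugRecord]:
    """Fill in SELFIES strings and token sequences for a drug list (in place).

    ``encoding="selfies"`` derives the SELFIES string from SMILES (unless
    already present) and tokenizes its bracket symbols; ``encoding="smiles"``
    tokenizes the raw SMILES string instead (the string-representation
    ablation). Token sequences longer than ``max_tokens`` keep their prefix.
    """
    for rec in records:
        if encoding == "selfies":
            if not rec.selfies:
                rec.selfies = encode_selfies(rec.smiles)
            tokens = tokenize_selfies(rec.selfies)
        elif encoding == "smiles":
            tokens = tokenize_smiles(rec.smiles)
        else:
            raise ValueError(f"unknown drug encoding {encoding!r}")
        rec.tokens = tuple(tokens[:max_tokens])
    return records


def drug_vectors(
    records: list[DrugRecord], params: EmbeddingParams | None = None
) -> tuple[np.ndarray, TokenEmbeddingTable]:
    """Train token embeddings on the drug corpus and pool one vector per drug."""
    table = train_token_embeddings([list(r.tokens) for r in records], params)
    vecs = np.stack([embed_drug(r, table) for r in records])
    return vecs, table


def drug_similarity_matrix(
    ids: list[str], vectors: np.ndarray
) -> SimilarityMatrix:
    """Cosine-similarity matrix S_D over pooled drug vectors, clipped to [0, 1]."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if len(ids) < 2:
        raise ValueError("need at least two drugs")
    norms = np.linalg.norm(vectors, axis=1)
    for i, nz in enumerate(norms):
        if nz == 0.0:
            raise ValueError(f"drug {ids[i]} has a zero-norm vector")
    unit = vectors / norms[:, None]
    values = _symmetrize_unit_diag(unit @ unit.T)
    return SimilarityMatrix(ids=list(ids), values=values, entity_kind="drug")
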