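"""Heterogeneous drug-protein network assembly.

The network over v drugs and m proteins is the (v+m) x (v+m) block matrix

    H_DP = [[ S_D,    A_DP ],
            [ A_DP.T, S_P  ]]

where A_DP is the binary known-interaction matrix. Each node's initial
feature vector is its row of H_DP, i.e. F_DP = H_DP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import InteractionTable
from .similarity import SimilarityMatrix


@dataclass
class HeteroNetwork:
    """Block adjacency over drug nodes (first) and protein nodes (last)."""

    drug_ids: list[str]
    protein_ids: list[str]
    H: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.drug_ids) + len(self.protein_ids)
        if self.H.shape != (n, n):
            raise ValueError("H shape inconsistent with node ids")
        self.node_index = {d: i for i, d in enumerate(self.drug_ids)}
        off = len(self.drug_ids)
        self.node_index.update({p: off + i for i, p in enumerate(self.protein_ids)})

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recover (S_D, A_DP, S_P) from the assembled matrix."""
        v = self.n_drugs
        return self.H[:v, :v], self.H[:v, v:], self.H[v:, v:]

    def to_tsv(self, path: str | Path) -> None:
        ids = self.drug_ids + self.protein_ids
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(ids) + "\n")
            for nid, row in zip(ids, self.H):
                fh.write(nid + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def build_hetnet(
    s_d: SimilarityMatrix,
    s_p: SimilarityMatrix,
    interactions: InteractionTable,
) -> HeteroNetwork:
    """Assemble H_DP from the two similarity blocks and the interaction edges.

    Any known drug-drug / target-target association edges present in
    ``interactions`` override the corresponding similarity entry to 1.
    Masking of held-out interaction edges is the caller's responsibility:
    only edges present in ``interactions.edges`` enter A_DP.
    """
    v, m = len(s_d.ids), len(s_p.ids)
    H = np.zeros((v + m, v + m))
    H[:v, :v] = s_d.values
    H[v:, v:] = s_p.values
    a = np.zeros((v, m))
    for d, p in interactions.edges:
        if d not in s_d._index:
            raise ValueError(f"interaction drug {d} missing from S_D")
        if p not in s_p._index:
            raise ValueError(f"interaction protein {p} missing from S_P")
        a[s_d.index_of(d), s_p.index_of(p)] = 1.0
    H[:v, v:] = a
    H[v:, :v] = a.T
    for x, y in interactions.drug_drug_edges:
        i, j = s_d.index_of(x), s_d.index_of(y)
        H[i, j] = H[j, i] = 1.0
    for x, y in interactions.target_target_edges:
        i, j = v + s_p.index_of(x), v + s_p.index_of(y)
        H[i, j] = H[j, i] = 1.0
    return HeteroNetwork(drug_ids=list(s_d.ids), protein_ids=list(s_p.ids), H=H)


def node_features(net: HeteroNetwork) -> np.ndarray:
    """Initial feature matrix F_DP: an independent copy of H_DP."""
    return net.H.copy()
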