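"""Synthetic drug/protein/interaction datasets with planted cluster structure.

Each of ``n_clusters`` clusters owns a drug scaffold (a short sequence of
valid SMILES fragments) and a protein sequence motif. Cluster members are
noisy copies: scaffold units and residues are point-mutated at rate
``sequence_noise``. Interactions are Bernoulli draws with probability
``interaction_prob_in`` for same-cluster (drug, protein) pairs and
``interaction_prob_out`` otherwise, so string similarity is genuinely
informative about interactions — the property the pipeline is supposed to
exploit. Generation is fully deterministic in the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .io_formats import (
    DrugRecord,
    InteractionTable,
    ProteinRecord,
    write_interactions,
)

#: SMILES fragments that stay valid under arbitrary concatenation
#: (every fragment's last atom has free valence for chain extension)
SCAFFOLD_UNITS = ("C", "O", "N", "CC", "c1ccccc1", "C=C", "CS", "C(=O)")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    n_drugs: int = 60
    n_proteins: int = 80
    n_clusters: int = 4
    motif_length: int = 30
    interaction_prob_in: float = 0.5
    interaction_prob_out: float = 0.02
    sequence_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > min(self.n_drugs, self.n_proteins):
            raise ValueError("more clusters than drugs or proteins")
        if not (self.interaction_prob_in > self.interaction_prob_out):
            raise ValueError("interaction_prob_in must exceed interaction_prob_out")
        for p in (self.interaction_prob_in, self.interaction_prob_out,
                  self.sequence_noise):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.motif_length < 1:
            raise ValueError("motif_length must be positive")


@dataclass
class SyntheticDataset:
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    interactions: InteractionTable
    drug_clusters: dict[str, int]
    protein_clusters: dict[str, int]
    config: SyntheticConfig


def _mutate_units(units: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = []
    for u in units:
        if rng.random() < rate:
            out.append(SCAFFOLD_UNITS[rng.integers(len(SCAFFOLD_UNITS))])
        else:
            out.append(u)
    return out


def _mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(chars)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate drugs, proteins and interactions with planted clusters.

    Every drug SMILES is validated through RDKit before being emitted.
    Protein sequences are a cluster motif flanked by random background
    (total length = motif_length + 90), then point-mutated.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    c = config.n_clusters

    # each cluster draws its scaffold from a signature-weighted unit mix, so
    # clusters are chemically distinct and string similarity carries the
    # planted structure
    n_units_total = len(SCAFFOLD_UNITS)
    scaffolds = []
    for k in range(c):
        weights = np.full(n_units_total, 0.05)
        weights[(2 * k) % n_units_total] += 0.45
        weights[(2 * k + 1) % n_units_total] += 0.45
        weights /= weights.sum()
        n_units = int(rng.integers(6, 13))
        scaffolds.append([SCAFFOLD_UNITS[i]
                          for i in rng.choice(n_units_total, size=n_units, p=weights)])
    motifs = [_random_sequence(config.motif_length, rng) for _ in range(c)]
    # shared flank background per cluster keeps within-cluster SW scores high
    flanks = [( _random_sequence(40, rng), _random_sequence(50, rng)) for _ in range(c)]

    drugs: list[DrugRecord] = []
    drug_clusters: dict[str, int] = {}
    for i in range(config.n_drugs):
        k = i % c
        units = _mutate_units(scaffolds[k], config.sequence_noise, rng)
        smiles = "".join(units)
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - units are safe
            raise RuntimeError(f"generated invalid SMILES {smiles!r}")
        did = f"d{i:03d}"
        drugs.append(DrugRecord(drug_id=did, smiles=smiles))
        drug_clusters[did] = k

    proteins: list[ProteinRecord] = []
    protein_clusters: dict[str, int] = {}
    for j in range(config.n_proteins):
        k = j % c
        left, right = flanks[k]
        seq = _mutate_sequence(left + motifs[k] + right, config.sequence_noise, rng)
        pid = f"p{j:03d}"
        proteins.append(ProteinRecord(protein_id=pid, sequence=seq))
        protein_clusters[pid] = k

    edges: set[tuple[str, str]] = set()
    for d in drugs:
        for p in proteins:
            same = drug_clusters[d.drug_id] == protein_clusters[p.protein_id]
            prob = config.interaction_prob_in if same else config.interaction_prob_out
            if rng.random() < prob:
                edges.add((d.drug_id, p.protein_id))

    return SyntheticDataset(
        drugs=drugs, proteins=proteins, interactions=InteractionTable(edges=edges),
        drug_clusters=drug_clusters, protein_clusters=protein_clusters, config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset in the package's own TSV/FASTA dialects plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "drugs.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tsmiles\n")
        for d in dataset.drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\n")
    with open(outdir / "proteins.fasta", "w", encoding="utf-8") as fh:
        for p in dataset.proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    write_interactions(dataset.interactions, outdir / "interactions.tsv")
    manifest = {
        "config": asdict(dataset.config),
        "drug_clusters": dataset.drug_clusters,
        "protein_clusters": dataset.protein_clusters,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                          encoding="utf-8")


# -- worked fixture --------------------------------------------------------


@dataclass
class WorkedFixture:
    """A tiny frozen dataset with every intermediate matrix precomputed.

    The stored matrices (S_D, S_P, H_DP, one GCN-layer output, and the token
    embedding table that produced S_D) were computed once by plain-python
    oracle implementations and serve as a regression surface for the
    similarity, network and encoder stages.
    """

    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    interactions: InteractionTable
    embedding_vocabulary: list[str]
    embedding_vectors: np.ndarray
    S_D: np.ndarray
    S_P: np.ndarray
    H_DP: np.ndarray
    gcn_output: np.ndarray  # one un-activated GCN layer with W = I


def generate_worked_fixture() -> WorkedFixture:
    """Load the frozen 3-drug / 4-protein worked example."""
    path = Path(__file__).parent / "data" / "worked_fixture.json"
    raw = json.loads(path.read_text(encoding="utf-8"))
    drugs = [DrugRecord(drug_id=d["drug_id"], smiles=d["smiles"],
                        selfies=d["selfies"], tokens=tuple(d["tokens"]))
             for d in raw["drugs"]]
    proteins = [ProteinRecord(**p) for p in raw["proteins"]]
    interactions = InteractionTable(edges={tuple(e) for e in raw["interactions"]})
    return WorkedFixture(
        drugs=drugs,
        proteins=proteins,
        interactions=interactions,
        embedding_vocabulary=list(raw["embedding"]["vocabulary"]),
        embedding_vectors=np.asarray(raw["embedding"]["vectors"]),
        S_D=np.asarray(raw["S_D"]),
        S_P=np.asarray(raw["S_P"]),
        H_DP=np.asarray(raw["H_DP"]),
        gcn_output=np.asarray(raw["gcn_output"]),
    )
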