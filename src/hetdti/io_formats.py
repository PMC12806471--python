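"""Readers and writers for the package's external file formats.

All tabular files are UTF-8 TSV with a header row; proteins may instead be
given as FASTA. The record types defined here are the shared currency of
every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: default cap on the number of SELFIES tokens kept per drug
MAX_DRUG_TOKENS = 100
#: default cap on protein sequence length (longer sequences keep their prefix)
MAX_PROTEIN_LENGTH = 300

#: the 20 standard amino acids; anything else is mapped to ``X``
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class DrugRecord:
    """One small molecule: identifier, SMILES, and its derived SELFIES form.

    ``selfies`` and ``tokens`` are empty until filled by
    :func:`hetdti.similarity.prepare_drugs`.
    """

    drug_id: str
    smiles: str
    selfies: str = ""
    tokens: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class ProteinRecord:
    """One protein target: identifier and (possibly truncated) sequence."""

    protein_id: str
    sequence: str


@dataclass
class InteractionTable:
    """Known drug-target interactions plus optional same-type association edges.

    Edges are stored undirected; same-type pairs are order-normalized so that
    ``(a, b)`` and ``(b, a)`` are the same edge.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    drug_drug_edges: set[tuple[str, str]] = field(default_factory=set)
    target_target_edges: set[tuple[str, str]] = field(default_factory=set)


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _read_table(path: str | Path, id_col: str, value_cols: Sequence[str]) -> list[dict]:
    """Read a TSV/CSV with a header; returns one dict per row.

    The delimiter is a tab for ``.tsv`` and a comma for ``.csv``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            rows.append(dict(zip(header, (p.strip() for p in parts))))
    if id_col not in header:
        raise FormatError(f"{path}: missing required column '{id_col}'")
    return rows


def read_drug_table(path: str | Path, format: str | None = None) -> list[DrugRecord]:
    """Read a drug table with columns ``drug_id`` and ``smiles`` (or ``selfies``).

    Rows are returned in file order. A ``selfies`` column, when present, is
    trusted as given; otherwise the SELFIES field is left empty to be filled
    during preprocessing.
    """
    rows = _read_table(path, "drug_id", ("smiles", "selfies"))
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for row in rows:
        drug_id = row["drug_id"]
        if not drug_id:
            raise FormatError(f"{path}: empty drug_id")
        if drug_id in seen:
            raise FormatError(f"duplicate drug_id {drug_id}")
        seen.add(drug_id)
        smiles = row.get("smiles", "")
        selfies = row.get("selfies", "")
        if not smiles and not selfies:
            raise FormatError(f"{path}: drug {drug_id} has neither smiles nor selfies")
        records.append(DrugRecord(drug_id=drug_id, smiles=smiles, selfies=selfies))
    return records


def normalize_sequence(seq: str) -> str:
    """Uppercase a residue string and map non-standard residues to ``X``."""
    seq = seq.upper()
    cleaned = []
    replaced = 0
    for ch in seq:
        if ch in STANDARD_AA:
            cleaned.append(ch)
        else:
            cleaned.append("X")
            replaced += 1
    if replaced:
        logger.warning("mapped %d non-standard residue(s) to X", replaced)
    return "".join(cleaned)


def read_proteins(
    path: str | Path,
    format: str | None = None,
    max_length: int = MAX_PROTEIN_LENGTH,
) -> list[ProteinRecord]:
    """Read proteins from FASTA or a TSV with columns (protein_id, sequence).

    Sequences are uppercased, non-standard residues become ``X``, and
    sequences longer than ``max_length`` keep only their prefix.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".faa"} else "tsv"
    pairs: list[tuple[str, str]] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            pairs.append((rec.id, str(rec.seq)))
    else:
        for row in _read_table(path, "protein_id", ("sequence",)):
            pairs.append((row["protein_id"], row.get("sequence", "")))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for pid, seq in pairs:
        if pid in seen:
            raise FormatError(f"duplicate protein_id {pid}")
        seen.add(pid)
        if not seq:
            raise FormatError(f"protein {pid}: empty sequence")
        seq = normalize_sequence(seq)[:max_length]
        records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_interactions(
    path: str | Path,
    drug_ids: Iterable[str] | None = None,
    protein_ids: Iterable[str] | None = None,
) -> InteractionTable:
    """Read a drug-target edge list (TSV columns drug_id, protein_id).

    Duplicated rows collapse to one edge. When ``drug_ids``/``protein_ids``
    are given, every endpoint must resolve to a loaded record.
    """
    rows = _read_table(path, "drug_id", ("protein_id",))
    known_d = set(drug_ids) if drug_ids is not None else None
    known_p = set(protein_ids) if protein_ids is not None else None
    edges: set[tuple[str, str]] = set()
    for row in rows:
        d, p = row["drug_id"], row.get("protein_id", "")
        if known_d is not None and d not in known_d:
            raise FormatError(f"interaction references unknown drug_id {d}")
        if known_p is not None and p not in known_p:
            raise FormatError(f"interaction references unknown protein_id {p}")
        edges.add((d, p))
    return InteractionTable(edges=edges)


def read_same_type_edges(path: str | Path, ids: Iterable[str] | None = None,
                         kind: str = "drug") -> set[tuple[str, str]]:
    """Read an optional drug-drug or target-target association edge list.

    Pairs are order-normalized; self-pairs are rejected.
    """
    col = "drug_id" if kind == "drug" else "protein_id"
    rows = _read_table(path, col, (col + "_2",))
    known = set(ids) if ids is not None else None
    edges: set[tuple[str, str]] = set()
    for row in rows:
        a, b = row[col], row.get(col + "_2", "")
        if a == b:
            raise FormatError(f"self-pair ({a}, {b}) not allowed")
        for x in (a, b):
            if known is not None and x not in known:
                raise FormatError(f"edge references unknown {col} {x}")
        edges.add(_norm_pair(a, b))
    return edges


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    """Write a drug-target edge list in the dialect ``read_interactions`` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\n")
        for d, p in sorted(table.edges):
            fh.write(f"{d}\t{p}\n")


def write_predictions(
    scores: Sequence[tuple[str, str, float]], path: str | Path
) -> None:
    """Write predicted pair scores as a TSV sorted by descending score.

    Ties are broken lexicographically by (drug_id, protein_id) so output is
    byte-deterministic.
    """
    for d, p, s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s!r} for ({d}, {p}) outside [0, 1]")
    ordered = sorted(scores, key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\tscore\n")
        for d, p, s in ordered:
            fh.write(f"{d}\t{p}\t{s:.6f}\n")
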