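"""A SELFIES-dialect string codec for neutral organic molecules.

SELFIES (self-referencing embedded strings) represents a molecular graph as
a sequence of bracketed symbols in which branches and rings carry explicit
length/offset annotations, so that every well-formed string corresponds to a
valid molecule. This module implements the encoder (SMILES -> SELFIES), the
symbol tokenizer, and a decoder used to verify round-trips, following the
v2 grammar conventions (hexadecimal index symbols, ``[BranchL]``/``[RingL]``
overloading).

Scope: uncharged organic molecules without isotopes, radicals or stereo
annotations — atoms B, C, N, O, S, P, F, Cl, Br, I with single, double and
triple bonds; aromatic systems are kekulized before encoding. Molecules
outside this subset raise :class:`SelfiesError`.
"""

from __future__ import annotations

import re

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")


class SelfiesError(ValueError):
    """Raised for molecules or strings outside the supported grammar."""


SUPPORTED_ELEMENTS = {"B", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}

_BOND_PREFIX = {Chem.BondType.SINGLE: "", Chem.BondType.DOUBLE: "=", Chem.BondType.TRIPLE: "#"}
_PREFIX_ORDER = {"": Chem.BondType.SINGLE, "=": Chem.BondType.DOUBLE, "#": Chem.BondType.TRIPLE}

# hexadecimal index alphabet: INDEX_SYMBOLS[i] encodes digit i
INDEX_SYMBOLS = [
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
]
_INDEX_OF = {s: i for i, s in enumerate(INDEX_SYMBOLS)}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_TOKEN_RE = re.compile(r"\[([=#]?)([A-Z][a-z]?)\]")
_BRANCH_TOKEN_RE = re.compile(r"\[([=#]?)Branch([123])\]")
_RING_TOKEN_RE = re.compile(r"\[([=#]?)Ring([123])\]")


def tokenize_selfies(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracket-delimited symbols.

    The concatenation of the returned tokens reproduces the input exactly;
    any character outside a balanced bracket pair is an error reported with
    its position.
    """
    tokens: list[str] = []
    pos = 0
    n = len(selfies)
    while pos < n:
        ch = selfies[pos]
        if ch != "[":
            raise SelfiesError(f"unexpected character {ch!r} at position {pos}")
        end = selfies.find("]", pos)
        if end == -1:
            raise SelfiesError(f"unbalanced bracket at position {n}")
        tokens.append(selfies[pos : end + 1])
        pos = end + 1
    return tokens


def _encode_index(q: int) -> list[str]:
    """Encode a nonnegative integer as big-endian hexadecimal index symbols."""
    digits = []
    while True:
        digits.append(INDEX_SYMBOLS[q % 16])
        q //= 16
        if q == 0:
            break
    return digits[::-1]


def _index_width(q: int) -> int:
    w = 1
    while q >= 16**w:
        w += 1
    return w


def _check_supported(mol: Chem.Mol, smiles: str) -> None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise SelfiesError(f"unsupported element {atom.GetSymbol()} in {smiles!r}")
        if atom.GetFormalCharge() != 0:
            raise SelfiesError(f"charged atoms not supported in {smiles!r}")
        if atom.GetIsotope() != 0:
            raise SelfiesError(f"isotopes not supported in {smiles!r}")
        if atom.GetNumRadicalElectrons() != 0:
            raise SelfiesError(f"radicals not supported in {smiles!r}")


def encode_selfies(smiles: str) -> str:
    """Convert a SMILES string to its SELFIES representation.

    Deterministic: the traversal starts at atom 0 of the RDKit molecule and
    visits neighbours in index order. Decoding the result yields a molecule
    with the same canonical structure as the input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesError(f"invalid SMILES: {smiles!r}")
    _check_supported(mol, smiles)
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    if mol.GetNumAtoms() == 0:
        raise SelfiesError(f"empty molecule: {smiles!r}")

    visited: dict[int, int] = {}  # atom idx -> derivation position
    used_bonds: set[int] = set()
    counter = [0]

    def neighbors(a: int) -> list[int]:
        return sorted(n.GetIdx() for n in mol.GetAtomWithIdx(a).GetNeighbors())

    def bond_prefix(a: int, b: int) -> str:
        bt = mol.GetBondBetweenAtoms(a, b).GetBondType()
        if bt not in _BOND_PREFIX:
            raise SelfiesError(f"unsupported bond type {bt} in {smiles!r}")
        return _BOND_PREFIX[bt]

    def emit_atom(a: int, prefix: str) -> list[str]:
        visited[a] = counter[0]
        counter[0] += 1
        return [f"[{prefix}{mol.GetAtomWithIdx(a).GetSymbol()}]"]

    def walk(a: int, prefix: str) -> list[str]:
        out = emit_atom(a, prefix)
        # ring-closure bonds to already-visited atoms, emitted at the later end
        for b in neighbors(a):
            if b in visited and b != a:
                bid = mol.GetBondBetweenAtoms(a, b).GetIdx()
                if bid in used_bonds:
                    continue
                used_bonds.add(bid)
                q = visited[a] - visited[b] - 1
                width = _index_width(q)
                out.append(f"[{bond_prefix(a, b)}Ring{width}]")
                out.extend(_encode_index(q))
        children = []
        for b in neighbors(a):
            bid = mol.GetBondBetweenAtoms(a, b).GetIdx()
            if b not in visited and bid not in used_bonds:
                children.append(b)
        for i, b in enumerate(children):
            # a neighbour may have been reached through a ring while a later
            # sibling's subtree was walked; re-check before descending
            if b in visited:
                continue
            bid = mol.GetBondBetweenAtoms(a, b).GetIdx()
            used_bonds.add(bid)
            pfx = bond_prefix(a, b)
            sub = walk(b, pfx)
            # wrap as a branch only if the chain must continue from this atom
            # (a later sibling may have been absorbed into the subtree via a ring)
            remaining = [c for c in children[i + 1 :] if c not in visited]
            if remaining:
                q = len(sub) - 1
                width = _index_width(q)
                out.append(f"[{pfx}Branch{width}]")
                out.extend(_encode_index(q))
            out.extend(sub)
        return out

    tokens = walk(0, "")
    if len(visited) != mol.GetNumAtoms():
        raise SelfiesError(f"disconnected molecules not supported: {smiles!r}")
    return "".join(tokens)


def decode_selfies(selfies: str) -> str:
    """Decode a SELFIES string produced by this codec into canonical SMILES."""
    tokens = tokenize_selfies(selfies)
    mol = Chem.RWMol()
    derived: list[int] = []  # rdkit atom indices in derivation order
    rings: list[tuple[int, int, Chem.BondType]] = []

    def read_index(stream: list[str], pos: int, width: int) -> tuple[int, int]:
        q = 0
        for _ in range(width):
            if pos >= len(stream):
                raise SelfiesError("truncated index after branch/ring symbol")
            sym = stream[pos]
            if sym not in _INDEX_OF:
                raise SelfiesError(f"invalid index symbol {sym}")
            q = q * 16 + _INDEX_OF[sym]
            pos += 1
        return q, pos

    def derive(stream: list[str], prev: int | None) -> None:
        pos = 0
        current = prev
        while pos < len(stream):
            tok = stream[pos]
            m = _BRANCH_TOKEN_RE.fullmatch(tok)
            if m:
                if current is None:
                    raise SelfiesError("branch with no preceding atom")
                q, pos2 = read_index(stream, pos + 1, int(m.group(2)))
                n_sym = q + 1
                branch = stream[pos2 : pos2 + n_sym]
                if len(branch) < n_sym:
                    raise SelfiesError("branch runs past end of string")
                derive(branch, current)
                pos = pos2 + n_sym
                continue
            m = _RING_TOKEN_RE.fullmatch(tok)
            if m:
                if current is None:
                    raise SelfiesError("ring with no preceding atom")
                q, pos = read_index(stream, pos + 1, int(m.group(2)))
                head = len(derived) - 1
                partner = head - (q + 1)
                if partner < 0:
                    raise SelfiesError(f"ring offset {q} reaches before the first atom")
                rings.append((derived[head], derived[partner], _PREFIX_ORDER[m.group(1)]))
                continue
            m = _ATOM_TOKEN_RE.fullmatch(tok)
            if m:
                prefix, symbol = m.groups()
                if symbol not in SUPPORTED_ELEMENTS:
                    raise SelfiesError(f"unsupported atom token {tok}")
                idx = mol.AddAtom(Chem.Atom(symbol))
                if current is not None:
                    mol.AddBond(current, idx, _PREFIX_ORDER[prefix])
                derived.append(idx)
                current = idx
                pos += 1
                continue
            raise SelfiesError(f"unrecognized token {tok}")

    derive(tokens, None)
    for a, b, order in rings:
        mol.AddBond(a, b, order)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - malformed hand-written input
        raise SelfiesError(f"decoded molecule failed sanitization: {exc}") from exc
    return Chem.MolToSmiles(out)


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string (raises on unparseable input)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


_SMILES_ATOM_RE = re.compile(r"Cl|Br|\[[^\]]*\]|[BCNOSPFIbcnosp]|.")


def tokenize_smiles(smiles: str) -> list[str]:
    """Tokenize a SMILES string into atom/bond/topology symbols.

    Used for the string-representation ablation in which drugs are embedded
    from SMILES tokens instead of SELFIES symbols.
    """
    tokens = _SMILES_ATOM_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise SelfiesError(f"could not tokenize SMILES {smiles!r}")
    return tokens
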