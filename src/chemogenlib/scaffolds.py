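"""Scaffold-tree decomposition.

Each molecule is reduced to its ring framework (the Murcko scaffold: ring
systems plus the linkers between them, with exocyclic double bonds on ring
atoms retained), then pruned one ring at a time down to a single ring.
The resulting chain of scaffolds is indexed by *level*: level 1 is the
full framework with R rings, level 2 has R-1 rings, and the terminal
level R has exactly one ring.  Scaffold identity is 2-D chemotype
identity: stereochemistry is stripped before canonicalisation, and every
scaffold is stored as a canonical SMILES so decompositions are
byte-identical across runs and platforms.

Which ring to prune when several could be removed is decided by a fixed
prioritisation cascade (an adaptation of the scaffold-tree pruning
priorities used by interactive scaffold browsers): keep heteroatom-rich
rings, prefer deleting large rings, prefer deleting rings attached by an
acyclic linker over fused rings, and finally break remaining ties by the
lexicographically smallest canonical SMILES of the resulting parent.  The
cascade is deterministic, so a given framework always yields the same
chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class ScaffoldContractError(ValueError):
    """An operation was called on input outside its contract."""


@dataclass(frozen=True)
class ScaffoldNode:
    """A canonical scaffold at one level of a molecule's decomposition chain.

    ``parent`` is the canonical SMILES of the next (smaller) scaffold in
    the chain, i.e. the one with one ring fewer, or ``None`` for the
    terminal single-ring scaffold.
    """

    scaffold_smiles: str
    level: int
    ring_count: int
    parent: str | None = None
    molecule_ids: frozenset[str] = frozenset()


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical, stereo-stripped SMILES."""
    mol = _parse(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _n_rings(mol: Chem.Mol) -> int:
    # cyclomatic number: the number of independent rings (SSSR size),
    # robust to the symmetrised ring perception of bridged cages
    n_frags = len(Chem.GetMolFrags(mol))
    return mol.GetNumBonds() - mol.GetNumAtoms() + n_frags


def ring_count(smiles: str) -> int:
    """Number of independent rings (smallest-set-of-smallest-rings size)."""
    return _n_rings(_parse(smiles))


def murcko_scaffold(smiles: str) -> str | None:
    """Ring framework of a molecule, or ``None`` for acyclic input.

    Terminal side chains are removed; linkers between ring systems and
    double bonds exocyclic to a ring atom (e.g. a ring ketone's oxygen)
    are kept.
    """
    mol = _parse(smiles)
    if _n_rings(mol) == 0:
        return None
    Chem.RemoveStereochemistry(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)


def _ring_atom_sets(mol: Chem.Mol) -> list[set[int]]:
    return [set(ring) for ring in mol.GetRingInfo().AtomRings()]


def _delete_ring(mol: Chem.Mol, ring: set[int], other_ring_atoms: set[int]) -> str | None:
    """Delete the atoms exclusive to one ring; return the cleaned parent SMILES.

    Returns ``None`` when the deletion does not produce a valid connected
    scaffold with exactly one ring fewer.
    """
    exclusive = sorted(ring - other_ring_atoms, reverse=True)
    if not exclusive:
        return None  # ring fully shared (bridged/fused envelope): not removable
    target_rings = _n_rings(mol) - 1
    # first attempt keeps aromatic flags so that e.g. the benzene left after
    # pruning one ring of naphthalene stays aromatic; kekulised fallback
    # covers rings whose remainder cannot be aromatic on its own
    for kekulize in (False, True):
        work = Chem.RWMol(mol)
        if kekulize:
            try:
                Chem.Kekulize(work, clearAromaticFlags=True)
            except Chem.KekulizeException:
                continue
        for idx in exclusive:
            work.RemoveAtom(idx)
        try:
            frag = work.GetMol()
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        frags = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(frags) != 1:
            return None
        scaffold = MurckoScaffold.GetScaffoldForMol(frag)
        if scaffold is None or scaffold.GetNumAtoms() == 0:
            continue
        if _n_rings(scaffold) != target_rings:
            continue
        return Chem.MolToSmiles(scaffold)
    return None


_HETERO = {"N", "O", "S", "P", "B", "Se", "Si", "As"}


@lru_cache(maxsize=65536)
def remove_one_ring(scaffold_smiles: str) -> str | None:
    """Prune one ring from a scaffold; ``None`` when a single ring remains.

    The pruned ring is chosen by the fixed cascade described in the module
    docstring; the result is the canonical SMILES of the parent scaffold,
    which has exactly one ring fewer.

    Raises
    ------
    ScaffoldContractError
        For acyclic input (not a scaffold).
    """
    mol = _parse(scaffold_smiles)
    Chem.RemoveStereochemistry(mol)
    n_rings = _n_rings(mol)
    if n_rings == 0:
        raise ScaffoldContractError(f"acyclic input is not a scaffold: {scaffold_smiles!r}")
    if n_rings == 1:
        return None

    rings = _ring_atom_sets(mol)
    candidates: list[tuple[tuple, str]] = []
    for i, ring in enumerate(rings):
        other_atoms = set().union(*(r for j, r in enumerate(rings) if j != i))
        parent = _delete_ring(mol, ring, other_atoms)
        if parent is None:
            continue
        n_hetero = sum(
            1 for idx in ring if mol.GetAtomWithIdx(idx).GetSymbol() in _HETERO
        )
        fused = bool(ring & other_atoms)
        # cascade: delete hetero-poor rings first, then larger rings, then
        # linker-attached before fused; parent SMILES breaks remaining ties
        key = (n_hetero, -len(ring), fused, parent)
        candidates.append((key, parent))
    if not candidates:
        # every single-ring deletion failed (e.g. heavily bridged systems):
        # fall back to the largest fragment after deleting each ring
        for i, ring in enumerate(rings):
            other_atoms = set().union(*(r for j, r in enumerate(rings) if j != i))
            parent = _delete_ring_keep_largest(mol, ring, other_atoms)
            if parent is not None:
                candidates.append(((0, 0, False, parent), parent))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def _delete_ring_keep_largest(
    mol: Chem.Mol, ring: set[int], other_ring_atoms: set[int]
) -> str | None:
    exclusive = sorted(ring - other_ring_atoms, reverse=True)
    if not exclusive:
        return None
    for kekulize in (False, True):
        work = Chem.RWMol(mol)
        if kekulize:
            try:
                Chem.Kekulize(work, clearAromaticFlags=True)
            except Chem.KekulizeException:
                continue
        for idx in exclusive:
            work.RemoveAtom(idx)
        try:
            frag = work.GetMol()
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        frags = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        frags = [f for f in frags if _n_rings(f) > 0]
        if not frags:
            continue
        best = max(frags, key=lambda f: (_n_rings(f), f.GetNumAtoms()))
        scaffold = MurckoScaffold.GetScaffoldForMol(best)
        if scaffold is None or scaffold.GetNumAtoms() == 0:
            continue
        return Chem.MolToSmiles(scaffold)
    return None


def scaffold_chain(smiles: str, molecule_id: str | None = None) -> list[ScaffoldNode]:
    """Full decomposition chain of a molecule, most-specific scaffold first.

    Returns an empty list for acyclic molecules.  For a framework with R
    rings the chain has R nodes with ring counts R, R-1, ..., 1.
    """
    framework = murcko_scaffold(smiles)
    if framework is None:
        return []
    members = frozenset({molecule_id}) if molecule_id is not None else frozenset()
    chain_smiles = [framework]
    current = framework
    while True:
        parent = remove_one_ring(current)
        if parent is None:
            break
        chain_smiles.append(parent)
        current = parent
    nodes = []
    for level, s in enumerate(chain_smiles, start=1):
        parent = chain_smiles[level] if level < len(chain_smiles) else None
        nodes.append(
            ScaffoldNode(
                scaffold_smiles=s,
                level=level,
                ring_count=ring_count(s),
                parent=parent,
                molecule_ids=members,
            )
        )
    return nodes


def level_scaffold(smiles: str, level: int) -> str | None:
    """Scaffold at a given chain level, or ``None`` if the chain is shorter.

    Level 1 is the Murcko framework itself.  With the default selection
    level of 2, molecules whose framework has a single ring have no
    level-2 scaffold and fall outside the scaffold-based selection path.
    """
    if level < 1:
        raise ScaffoldContractError(f"level must be >= 1, got {level}")
    chain = scaffold_chain(smiles)
    if len(chain) < level:
        return None
    return chain[level - 1].scaffold_smiles


def scaffold_table(molecules: Mapping[str, str]) -> "pd.DataFrame":
    """Decompose a set of molecules into a long-form scaffold table.

    Columns: molecule_id, level, scaffold_smiles, ring_count,
    parent_scaffold.  Acyclic molecules contribute no rows.
    """
    import pandas as pd

    rows = []
    for mol_id, smiles in molecules.items():
        for node in scaffold_chain(smiles, mol_id):
            rows.append(
                {
                    "molecule_id": mol_id,
                    "level": node.level,
                    "scaffold_smiles": node.scaffold_smiles,
                    "ring_count": node.ring_count,
                    "parent_scaffold": node.parent or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "level", "scaffold_smiles", "ring_count", "parent_scaffold"],
    )


def level_scaffold_map(molecules: Mapping[str, str], level: int = 2) -> dict[str, str]:
    """molecule_id -> scaffold SMILES at the given level (absent if chain too short)."""
    out = {}
    for mol_id, smiles in molecules.items():
        s = level_scaffold(smiles, level)
        if s is not None:
            out[mol_id] = s
    return out
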