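"""Candidate substructure enumeration.

Five generation strategies produce fragment patterns from a labelled
dataset: atom-centred circular environments (Morgan-style), linear
bond paths, heteroatom/aromatic functional groups, recursive acyclic
bond breaking (SARpy-style), and matching against a predefined SMARTS
catalogue (KRFP-style). All strategies share one support-counting
semantics: a fragment is counted at most once per molecule, and a
molecule "contains" a fragment iff the pattern has at least one
substructure embedding in it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

from .chem_io import MoleculeRecord, PatternCatalogue, ToxicityDataset

STRATEGIES = ("circular", "path", "group", "bondbreak", "catalogue")


@dataclass(frozen=True)
class FragmentKey:
    """A substructure pattern plus the strategy that produced it.

    ``pattern`` is either a canonical fragment SMILES (usable directly as a
    substructure query) or a SMARTS string for catalogue fragments.
    """

    pattern: str
    origin: str


@dataclass(frozen=True)
class AlertSupport:
    """Per-fragment support counts on a dataset: N_sub and N_sub-positive."""

    n_sub: int
    n_sub_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_sub_positive <= self.n_sub):
            raise ValueError(f"inconsistent support: {self}")


@dataclass
class FragmentTable:
    """Dataset-level fragment support counts for one mining strategy."""

    dataset_ref: str
    rows: dict[FragmentKey, AlertSupport] = field(default_factory=dict)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.rows)


@lru_cache(maxsize=200_000)
def compile_query(pattern: str, smarts: bool = False) -> Chem.Mol:
    """Compile a fragment pattern into an RDKit substructure query.

    Mined fragment patterns are canonical SMILES and are matched as
    molecule queries, which ignores hydrogen-count artifacts introduced
    when a fragment is cut out of its parent (attachment-free matching).
    Catalogue patterns are genuine SMARTS and keep full SMARTS semantics
    (``smarts=True``). Partial aromatic fragments that are not valid
    molecules fall back to SMARTS, then to an unsanitized parse.
    """
    if smarts:
        q = Chem.MolFromSmarts(pattern)
        if q is None:
            raise ValueError(f"pattern does not compile as SMARTS: {pattern!r}")
        return q
    q = Chem.MolFromSmiles(pattern)
    if q is not None:
        # unfilled valences at former attachment points become radical
        # electrons on parsing; clear them so matching stays attachment-free
        for atom in q.GetAtoms():
            atom.SetNumRadicalElectrons(0)
        return q
    q = Chem.MolFromSmarts(pattern)
    if q is None:
        q = Chem.MolFromSmiles(pattern, sanitize=False)
        if q is not None:
            q.UpdatePropertyCache(strict=False)
    if q is None:
        raise ValueError(f"pattern does not compile as a query: {pattern!r}")
    return q


def matches(mol: Chem.Mol, pattern: str, smarts: bool = False) -> bool:
    return mol.HasSubstructMatch(compile_query(pattern, smarts))


def _fragment_smiles(mol: Chem.Mol, bond_ids) -> str | None:
    """Canonical SMILES of the subgraph induced by a set of bonds."""
    bond_ids = list(bond_ids)
    if not bond_ids:
        return None
    atoms: set[int] = set()
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    try:
        return Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(atoms), bondsToUse=bond_ids, canonical=True
        )
    except Exception:  # pragma: no cover - malformed subgraph
        return None


def enumerate_circular(mol: Chem.Mol, r_min: int = 1, r_max: int = 4) -> set[FragmentKey]:
    """Atom-centred environments at every bond radius in [r_min, r_max].

    The radius counts bonds, so an isolated atom yields nothing; an
    environment that saturates the molecule before r_max is emitted once.
    """
    if not (1 <= r_min <= r_max):
        raise ValueError("require 1 <= r_min <= r_max")
    out: set[FragmentKey] = set()
    for atom in mol.GetAtoms():
        for radius in range(r_min, r_max + 1):
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom.GetIdx())
            if not env:
                break  # no environment of exactly this radius; larger radii are empty too
            smi = _fragment_smiles(mol, env)
            if smi:
                out.add(FragmentKey(pattern=smi, origin="circular"))
    return out


def enumerate_paths(mol: Chem.Mol, l_min: int = 1, l_max: int = 7) -> set[FragmentKey]:
    """Simple linear paths of l_min..l_max bonds; a path and its reverse are one fragment."""
    if not (1 <= l_min <= l_max):
        raise ValueError("require 1 <= l_min <= l_max")
    out: set[FragmentKey] = set()
    for length in range(l_min, l_max + 1):
        for path in Chem.FindAllPathsOfLengthN(mol, length, useBonds=True):
            bond_ids = list(path)
            # reject walks that revisit an atom (ring round-trips): a linear
            # path of k bonds spans exactly k+1 distinct atoms
            atoms: set[int] = set()
            for b in bond_ids:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            if len(atoms) != length + 1:
                continue
            smi = _fragment_smiles(mol, bond_ids)
            if smi:
                out.add(FragmentKey(pattern=smi, origin="path"))
    return out


def _aromatic_ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused aromatic ring systems as atom-index sets."""
    ri = mol.GetRingInfo()
    systems: list[set[int]] = []
    for ring in ri.AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        ring_set = set(ring)
        merged = False
        for sys_atoms in systems:
            if sys_atoms & ring_set:
                sys_atoms |= ring_set
                merged = True
                break
        if not merged:
            systems.append(ring_set)
    # a second pass merges systems joined through a later ring
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(systems), 2):
            if a in systems and b in systems and a & b:
                systems.remove(b)
                a |= b
                changed = True
    return systems


def enumerate_groups(mol: Chem.Mol) -> set[FragmentKey]:
    """Functional groups seeded on heteroatoms and carbons multiply bonded to them.

    Adjacent non-aromatic seed atoms merge into one group, which then
    absorbs its multiply-bonded neighbours (so a carbonyl keeps its oxygen).
    Aromatic ring systems are emitted whole; plain carbon skeleton atoms are
    never emitted alone.
    """
    out: set[FragmentKey] = set()
    for sys_atoms in _aromatic_ring_systems(mol):
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in sys_atoms and b.GetEndAtomIdx() in sys_atoms
        ]
        smi = _fragment_smiles(mol, bonds)
        if smi:
            out.add(FragmentKey(pattern=smi, origin="group"))

    def is_multiple(bond: Chem.Bond) -> bool:
        return bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)

    seeds: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            continue  # aromatic atoms belong to their ring-system pattern
        if atom.GetAtomicNum() not in (1, 6):
            seeds.add(atom.GetIdx())
        elif atom.GetAtomicNum() == 6:
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom)
                if is_multiple(bond) and other.GetAtomicNum() not in (1, 6):
                    seeds.add(atom.GetIdx())
                    break
    # connected components over seed adjacency
    remaining = set(seeds)
    while remaining:
        start = remaining.pop()
        component = {start}
        frontier = [start]
        while frontier:
            idx = frontier.pop()
            for bond in mol.GetAtomWithIdx(idx).GetBonds():
                other = bond.GetOtherAtomIdx(idx)
                if other in remaining:
                    remaining.discard(other)
                    component.add(other)
                    frontier.append(other)
        # absorb multiply-bonded neighbours of the component
        extra: set[int] = set()
        for idx in component:
            for bond in mol.GetAtomWithIdx(idx).GetBonds():
                if is_multiple(bond):
                    extra.add(bond.GetOtherAtomIdx(idx))
        group = component | extra
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in group and b.GetEndAtomIdx() in group
        ]
        if bonds:
            smi = _fragment_smiles(mol, bonds)
        else:
            # single-atom group, e.g. a phenolic oxygen
            smi = Chem.MolFragmentToSmiles(mol, atomsToUse=list(group), canonical=True)
        if smi:
            out.add(FragmentKey(pattern=smi, origin="group"))
    return out


def _breakable_bonds(mol: Chem.Mol) -> list[int]:
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def enumerate_bondbreak(
    mol: Chem.Mol,
    min_atoms: int = 2,
    max_atoms: int = 15,
    max_breaks: int = 3,
    fragment_cap: int = 10_000,
) -> set[FragmentKey]:
    """Recursive acyclic single-bond breaking, SARpy style.

    All combinations of up to ``max_breaks`` simultaneous acyclic single-bond
    cuts are applied; every connected product with a heavy-atom count in
    [min_atoms, max_atoms] becomes a candidate. Enumeration proceeds
    breadth-first by the number of broken bonds and truncates
    deterministically at ``fragment_cap`` distinct fragments per molecule.
    """
    if not (2 <= min_atoms <= max_atoms):
        raise ValueError("require 2 <= min_atoms <= max_atoms")
    bonds = _breakable_bonds(mol)
    out: set[FragmentKey] = set()

    def emit(m: Chem.Mol) -> bool:
        """Add qualifying connected fragments; False once the cap is hit."""
        for frag in Chem.GetMolFrags(m, asMols=True, sanitizeFrags=False):
            if min_atoms <= frag.GetNumHeavyAtoms() <= max_atoms:
                try:
                    Chem.SanitizeMol(frag)
                    smi = Chem.MolToSmiles(frag)
                except Exception:
                    continue
                out.add(FragmentKey(pattern=smi, origin="bondbreak"))
                if len(out) >= fragment_cap:
                    return False
        return True

    if not emit(mol):
        return out
    for k in range(1, max_breaks + 1):
        for combo in itertools.combinations(bonds, k):
            broken = Chem.FragmentOnBonds(mol, list(combo), addDummies=False)
            if not emit(broken):
                warnings.warn(
                    f"bondbreak fragment cap {fragment_cap} reached; truncated", stacklevel=2
                )
                return out
    return out


_STRATEGY_DEFAULTS = {
    "circular": {"r_min": 1, "r_max": 4},
    "path": {"l_min": 1, "l_max": 7},
    "group": {},
    "bondbreak": {"min_atoms": 2, "max_atoms": 15},
}


def fragments_for_molecule(mol: Chem.Mol, strategy: str, **params) -> set[FragmentKey]:
    """Dispatch per-molecule enumeration for one strategy."""
    if strategy == "circular":
        return enumerate_circular(mol, **params)
    if strategy == "path":
        return enumerate_paths(mol, **params)
    if strategy == "group":
        return enumerate_groups(mol, **params)
    if strategy == "bondbreak":
        return enumerate_bondbreak(mol, **params)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def match_catalogue(dataset: ToxicityDataset, cat: PatternCatalogue) -> FragmentTable:
    """Support counts of every catalogue pattern over the dataset.

    Patterns matching no compound are absent from the table.
    """
    table = FragmentTable(dataset_ref=dataset.endpoint)
    queries = [(p, compile_query(p, smarts=True)) for p in cat.patterns]
    counts: dict[str, list[int]] = {p: [0, 0] for p in cat.patterns}
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            table.n_skipped += 1
            continue
        for pattern, query in queries:
            if mol.HasSubstructMatch(query):
                counts[pattern][0] += 1
                counts[pattern][1] += rec.label
    for pattern in cat.patterns:
        n_sub, n_pos = counts[pattern]
        if n_sub > 0:
            table.rows[FragmentKey(pattern=pattern, origin="catalogue")] = AlertSupport(
                n_sub=n_sub, n_sub_positive=n_pos
            )
    return table


def build_table(
    dataset: ToxicityDataset,
    strategy: str,
    strategy_params: dict | None = None,
    catalogue: PatternCatalogue | None = None,
) -> FragmentTable:
    """Union per-molecule fragment sets into dataset-level support counts.

    Deterministic for a fixed dataset ordering; molecules whose SMILES fail
    to parse are skipped and tallied. An empty table is a data outcome, not
    an error (some strategies legitimately find nothing).
    """
    if strategy == "catalogue":
        if catalogue is None:
            raise ValueError("catalogue strategy requires a PatternCatalogue")
        return match_catalogue(dataset, catalogue)
    params = dict(_STRATEGY_DEFAULTS.get(strategy, {}))
    params.update(strategy_params or {})
    table = FragmentTable(dataset_ref=dataset.endpoint)
    counts: dict[FragmentKey, list[int]] = {}
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            warnings.warn(f"skipping unparseable SMILES for {rec.id}", stacklevel=2)
            table.n_skipped += 1
            continue
        for key in fragments_for_molecule(mol, strategy, **params):
            c = counts.setdefault(key, [0, 0])
            c[0] += 1
            c[1] += rec.label
    for key in sorted(counts, key=lambda k: k.pattern):
        n_sub, n_pos = counts[key]
        table.rows[key] = AlertSupport(n_sub=n_sub, n_sub_positive=n_pos)
    return table
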