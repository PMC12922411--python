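"""Consensus (benchmark) alert sets across mining strategies.

Different strategies emit the same chemistry in different spellings
(SMARTS decorations, atom maps, sub/super-structures of one toxicophore).
Building a benchmark set therefore proceeds in three steps:

1. normalize every pattern to a canonical SMILES, stripping atom maps and
   reducible query decorations;
2. consolidate: whenever one pattern is a substructure of another, the
   pair collapses to the simpler pattern (fewer heavy atoms), applied to a
   fixed point;
3. intersect the consolidated sets of every strategy that produced at
   least ``min_set_size`` alerts (less productive strategies are excluded).

Pairwise overlap counting and top-k comparison against a reference
catalogue use the same normalization so all analyses are consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .alert_filtering import AlertSet
from .alert_scoring import rank_top_k
from .chem_io import PatternCatalogue
from .fragment_mining import compile_query


@dataclass
class NormalizedAlert:
    """A pattern reduced to a canonical form, with the strategies that produced it."""

    canonical: str
    sources: set[str] = field(default_factory=set)
    heavy_atoms: int = 0
    is_query_only: bool = False  # could not be reduced to a plain molecule


@dataclass
class ConsensusSet:
    endpoint: str
    included_strategies: list[str] = field(default_factory=list)
    excluded_strategies: list[str] = field(default_factory=list)
    benchmark: list[NormalizedAlert] = field(default_factory=list)
    overlap: "np.ndarray | None" = None
    overlap_strategies: list[str] = field(default_factory=list)
    note: str | None = None


def _query_mol(pattern: str) -> Chem.Mol | None:
    q = Chem.MolFromSmarts(pattern)
    if q is None:
        q = Chem.MolFromSmiles(pattern, sanitize=False)
    if q is not None:
        try:
            q.UpdatePropertyCache(strict=False)
        except Exception:
            return None
    return q


def normalize(pattern: str, sources: set[str] | None = None) -> NormalizedAlert:
    """Strip atom maps / reducible query decorations and emit canonical SMILES.

    Patterns whose query atoms cannot be reduced to plain atoms (e.g.
    aromatic partial-ring fragments) keep a documented canonical text form:
    the RDKit canonical ordering of the un-sanitized fragment.
    """
    mol = Chem.MolFromSmiles(pattern)
    if mol is not None:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum():
                # mapped atoms come from reaction/position markup: drop the
                # bracket-atom H/valence constraints along with the map
                atom.SetAtomMapNum(0)
                atom.SetNumRadicalElectrons(0)
                if atom.GetNumExplicitHs() == 0:
                    atom.SetNoImplicit(False)
            atom.SetNumRadicalElectrons(0)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            pass
        canonical = Chem.MolToSmiles(mol)
        return NormalizedAlert(
            canonical=canonical,
            sources=set(sources or ()),
            heavy_atoms=mol.GetNumHeavyAtoms(),
        )
    # not a valid molecule: try query-level parse, strip maps, re-canonicalize
    q = _query_mol(pattern)
    if q is None:
        raise ValueError(f"pattern does not parse: {pattern!r}")
    for atom in q.GetAtoms():
        atom.SetAtomMapNum(0)
    try:
        mol2 = Chem.Mol(q)
        Chem.SanitizeMol(mol2)
        canonical = Chem.MolToSmiles(mol2)
        return NormalizedAlert(
            canonical=canonical,
            sources=set(sources or ()),
            heavy_atoms=mol2.GetNumHeavyAtoms(),
        )
    except Exception:
        canonical = Chem.MolToSmiles(q, canonical=True)
        return NormalizedAlert(
            canonical=canonical,
            sources=set(sources or ()),
            heavy_atoms=q.GetNumAtoms(),
            is_query_only=True,
        )


def _num_rings(pattern: str) -> int:
    q = _query_mol(pattern)
    if q is None:
        return 0
    try:
        Chem.FastFindRings(q)
        return q.GetRingInfo().NumRings()
    except Exception:
        return 0


def _includes(container: str, contained: str) -> bool:
    """True iff ``contained`` has an embedding in ``container``."""
    host = _query_mol(container)
    if host is None:
        return False
    try:
        return host.HasSubstructMatch(compile_query(contained))
    except Exception:
        return False


def _simpler(a: NormalizedAlert, b: NormalizedAlert) -> NormalizedAlert:
    """Deterministic 'simpler' choice: fewer heavy atoms, then fewer rings, then lexicographic."""
    ka = (a.heavy_atoms, _num_rings(a.canonical), a.canonical)
    kb = (b.heavy_atoms, _num_rings(b.canonical), b.canonical)
    return a if ka <= kb else b


def consolidate(alerts: list[NormalizedAlert]) -> list[NormalizedAlert]:
    """Collapse inclusion-related patterns to the simpler one, to a fixed point.

    Exact duplicates merge first (sources unioned). The result is
    order-independent because candidates are processed in a sorted order
    and merging is applied until no pair is inclusion-related.
    """
    # merge exact duplicates
    by_canonical: dict[str, NormalizedAlert] = {}
    for a in alerts:
        if a.canonical in by_canonical:
            by_canonical[a.canonical].sources |= a.sources
        else:
            by_canonical[a.canonical] = NormalizedAlert(
                canonical=a.canonical,
                sources=set(a.sources),
                heavy_atoms=a.heavy_atoms,
                is_query_only=a.is_query_only,
            )
    pool = sorted(by_canonical.values(), key=lambda a: (a.heavy_atoms, a.canonical))
    changed = True
    while changed:
        changed = False
        n = len(pool)
        for i in range(n):
            if changed:
                break
            for j in range(i + 1, n):
                a, b = pool[i], pool[j]
                if _includes(a.canonical, b.canonical) or _includes(b.canonical, a.canonical):
                    keep = _simpler(a, b)
                    drop = b if keep is a else a
                    keep.sources |= drop.sources
                    pool = [p for p in pool if p is not drop]
                    changed = True
                    break
    return sorted(pool, key=lambda a: (a.heavy_atoms, a.canonical))


def _normalized_set(alerts: AlertSet) -> list[NormalizedAlert]:
    out = []
    for a in alerts.alerts:
        out.append(normalize(a.key.pattern, sources={alerts.strategy or a.key.origin}))
    return out


def build_benchmark(sets: dict[str, AlertSet], min_set_size: int = 20) -> ConsensusSet:
    """Benchmark alerts = consolidated patterns present in every productive strategy.

    Strategies with fewer than ``min_set_size`` alerts are excluded before
    intersecting; an empty intersection is a legitimate outcome.
    """
    if not sets:
        raise ValueError("need at least one strategy alert set")
    endpoint = next(iter(sets.values())).endpoint
    included = sorted(s for s, a in sets.items() if len(a) >= min_set_size)
    excluded = sorted(s for s in sets if s not in included)
    result = ConsensusSet(
        endpoint=endpoint, included_strategies=included, excluded_strategies=excluded
    )
    if not included:
        result.note = f"all strategies produced fewer than {min_set_size} alerts"
        return result
    consolidated = {
        s: consolidate(_normalized_set(sets[s])) for s in included
    }
    common: set[str] | None = None
    for s in included:
        canon = {a.canonical for a in consolidated[s]}
        common = canon if common is None else common & canon
    assert common is not None
    benchmark: dict[str, NormalizedAlert] = {}
    for s in included:
        for a in consolidated[s]:
            if a.canonical in common:
                if a.canonical in benchmark:
                    benchmark[a.canonical].sources |= a.sources
                else:
                    benchmark[a.canonical] = a
    result.benchmark = sorted(benchmark.values(), key=lambda a: (a.heavy_atoms, a.canonical))
    return result


def pairwise_overlap(sets: dict[str, AlertSet]) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of identical (normalized-consolidated) alerts per strategy pair.

    The diagonal holds each strategy's own consolidated set size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two strategies for overlap counting")
    strategies = sorted(sets)
    consolidated = {s: {a.canonical for a in consolidate(_normalized_set(sets[s]))} for s in strategies}
    n = len(strategies)
    matrix = np.zeros((n, n), dtype=int)
    for i, si in enumerate(strategies):
        for j, sj in enumerate(strategies):
            if i == j:
                matrix[i, j] = len(consolidated[si])
            else:
                matrix[i, j] = len(consolidated[si] & consolidated[sj])
    return matrix, strategies


@dataclass
class ReferenceComparison:
    """Top-k alerts versus a reference catalogue, matched by identity or inclusion."""

    endpoint: str
    k: int
    matched: list[tuple[str, str, str]] = field(default_factory=list)  # (pattern, relation, ref)
    unmatched: list[str] = field(default_factory=list)

    @property
    def overlap_count(self) -> int:
        return len(self.matched)


def compare_to_reference(
    alerts: AlertSet, ref: PatternCatalogue, k: int = 10
) -> ReferenceComparison:
    """Report which of the top-k (by IG) alerts equal / are contained in / contain a reference pattern."""
    report = ReferenceComparison(endpoint=alerts.endpoint, k=k)
    if not alerts.alerts:
        return report
    top = rank_top_k(alerts.alerts, k)
    for a in top:
        pattern = a.key.pattern
        match: tuple[str, str, str] | None = None
        for ref_pattern in ref.patterns:
            contained = _includes(ref_pattern, pattern)
            contains = _includes(pattern, ref_pattern)
            if contained and contains:
                match = (pattern, "equal", ref_pattern)
            elif contained:
                match = (pattern, "contained_in", ref_pattern)
            elif contains:
                match = (pattern, "contains", ref_pattern)
            if match:
                break
        if match:
            report.matched.append(match)
        else:
            report.unmatched.append(pattern)
    return report
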