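"""Reading, cleaning and canonicalizing labelled compound tables.

The unit of every downstream statistic is the distinct molecule: input
tables are washed (largest covalent fragment kept), canonicalized and
deduplicated before any fragment is counted, so ``n_total`` always refers
to distinct canonical SMILES.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

_TRUE_LABELS = {"1", 1, True}
_FALSE_LABELS = {"0", 0, False}


class DataError(ValueError):
    """Fatal problem with an input file (missing columns, nothing parseable)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A single compound: opaque id, canonical SMILES and binary toxicity label."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"record {self.id}: unparseable SMILES {self.smiles!r}")
        return m


@dataclass
class ToxicityDataset:
    """A named endpoint: an ordered, duplicate-free collection of records.

    ``n_total`` is the denominator of the coverage rate and the universe of
    the binomial significance test; ``n_positive`` the number of toxic
    compounds.
    """

    endpoint: str
    records: list[MoleculeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.smiles in seen:
                raise ValueError(f"duplicate canonical SMILES in dataset: {r.smiles}")
            seen.add(r.smiles)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.label for r in self.records)

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive

    def subset(self, indices: Sequence[int], endpoint: str | None = None) -> "ToxicityDataset":
        return ToxicityDataset(
            endpoint=endpoint or self.endpoint,
            records=[self.records[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_dataset`: what was dropped and why."""

    n_input_rows: int = 0
    n_unparseable: int = 0
    n_duplicates_merged: int = 0
    n_conflicts_dropped: int = 0


@dataclass
class PatternCatalogue:
    """A named, ordered list of unique valid SMARTS patterns (KRFP-style)."""

    name: str
    patterns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patterns)


def canonical_smiles(smiles: str) -> str | None:
    """Canonicalize a SMILES string; ``None`` if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def wash_smiles(smiles: str) -> str | None:
    """Strip salts/solvents: keep the covalent fragment with the most heavy atoms.

    Ties are broken by lexicographic order of the fragments' canonical
    SMILES, so washing is deterministic. Returns canonical SMILES of the
    kept fragment, or ``None`` for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    keyed = []
    for f in frags:
        smi = Chem.MolToSmiles(f)
        keyed.append((f.GetNumHeavyAtoms(), smi))
    # max heavy atoms; ties -> lexicographically smallest canonical SMILES
    keyed.sort(key=lambda t: (-t[0], t[1]))
    return keyed[0][1]


def coerce_label(value) -> int:
    """Map an accepted label spelling to {0,1}; anything else is an error."""
    if isinstance(value, float):
        if math.isnan(value):
            raise ValueError("label is missing (NaN)")
        if value in (0.0, 1.0):
            return int(value)
        raise ValueError(f"unrecognized label {value!r}")
    if isinstance(value, str):
        value = value.strip().lower()
        if value in ("true",):
            return 1
        if value in ("false",):
            return 0
    if value in _TRUE_LABELS:
        return 1
    if value in _FALSE_LABELS:
        return 0
    raise ValueError(f"unrecognized label {value!r}")


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def dataset_from_rows(
    rows: Iterable[tuple[str, object]],
    endpoint: str,
    report: LoadReport | None = None,
) -> ToxicityDataset:
    """Wash, canonicalize and deduplicate ``(smiles, label)`` rows.

    Duplicate canonical SMILES with agreeing labels merge to one record;
    with conflicting labels the compound is dropped entirely.
    """
    report = report if report is not None else LoadReport()
    labels_by_smiles: dict[str, set[int]] = {}
    order: list[str] = []
    for smiles, raw_label in rows:
        report.n_input_rows += 1
        label = coerce_label(raw_label)
        washed = wash_smiles(str(smiles))
        if washed is None:
            report.n_unparseable += 1
            continue
        if washed not in labels_by_smiles:
            labels_by_smiles[washed] = set()
            order.append(washed)
        else:
            report.n_duplicates_merged += 1
        labels_by_smiles[washed].add(label)
    records = []
    for i, smi in enumerate(order):
        labels = labels_by_smiles[smi]
        if len(labels) > 1:
            report.n_conflicts_dropped += 1
            continue
        records.append(MoleculeRecord(id=f"{endpoint}:{i}", smiles=smi, label=labels.pop()))
    return ToxicityDataset(endpoint=endpoint, records=records)


def load_dataset(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: str = "label",
    endpoint: str | None = None,
    sep: str | None = None,
) -> tuple[ToxicityDataset, LoadReport]:
    """Load a labelled compound table (CSV/TSV) into a clean dataset.

    Every row is washed to its largest covalent fragment, canonicalized
    and deduplicated on canonical SMILES. Unparseable rows are dropped and
    counted; duplicates with conflicting labels drop the compound.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=sep or _infer_sep(path), dtype={smiles_col: str}, keep_default_na=False)
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    if len(df) == 0:
        raise DataError(f"input file is empty: {path}")
    report = LoadReport()
    dataset = dataset_from_rows(
        zip(df[smiles_col], df[label_col]),
        endpoint=endpoint or path.stem,
        report=report,
    )
    if dataset.n_total == 0 and report.n_conflicts_dropped == 0:
        raise DataError(f"no parseable SMILES rows in {path}")
    return dataset, report


_ALERT_COLUMNS = ["pattern", "n_sub", "n_sub_positive", "pr", "cr", "ig", "p_value", "strategy"]


def write_alert_set(alerts, path: str | Path) -> None:
    """Write a scored alert set to CSV (one row per pattern); round-trips losslessly."""
    path = Path(path)
    rows = [
        {
            "pattern": a.key.pattern,
            "n_sub": a.support.n_sub,
            "n_sub_positive": a.support.n_sub_positive,
            "pr": a.pr,
            "cr": a.cr,
            "ig": a.ig,
            "p_value": a.p_value,
            "strategy": a.key.origin,
        }
        for a in alerts.alerts
    ]
    df = pd.DataFrame(rows, columns=_ALERT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def load_alert_set(path: str | Path, endpoint: str = ""):
    """Read an alert-set CSV written by :func:`write_alert_set`."""
    from .alert_filtering import AlertSet
    from .alert_scoring import ScoredAlert
    from .fragment_mining import AlertSupport, FragmentKey

    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _ALERT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"alert file {path} is missing columns {missing}")
    alerts = []
    for row in df.itertuples(index=False):
        alerts.append(
            ScoredAlert(
                key=FragmentKey(pattern=row.pattern, origin=row.strategy),
                support=AlertSupport(n_sub=int(row.n_sub), n_sub_positive=int(row.n_sub_positive)),
                pr=float(row.pr),
                cr=float(row.cr),
                ig=float(row.ig),
                p_value=float(row.p_value),
            )
        )
    strategy = alerts[0].key.origin if alerts else ""
    return AlertSet(endpoint=endpoint or path.stem, strategy=strategy, alerts=alerts)


def load_catalogue(path: str | Path, name: str | None = None) -> PatternCatalogue:
    """Read a SMARTS pattern list (one per line, ``#`` comments allowed).

    Invalid SMARTS are rejected with their line numbers; duplicate
    patterns collapse to the first occurrence. A file with no valid
    pattern at all is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"catalogue file not found: {path}")
    patterns: list[str] = []
    seen: set[str] = set()
    bad_lines: list[int] = []
    n_candidates = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        n_candidates += 1
        if Chem.MolFromSmarts(text) is None:
            bad_lines.append(lineno)
            continue
        if text not in seen:
            seen.add(text)
            patterns.append(text)
    if n_candidates > 0 and not patterns:
        raise DataError(f"no valid SMARTS in {path}; invalid lines: {bad_lines}")
    return PatternCatalogue(name=name or path.stem, patterns=patterns)
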