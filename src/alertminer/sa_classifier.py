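"""Alert sets as binary classifiers.

A set of structural alerts predicts "toxic" for any molecule containing at
least one alert pattern. The evaluation protocol is five repetitions of a
random 8:2 train/test split: alerts are mined on the training split only,
then scored on both splits with ACC, PPV and MCC:

    ACC = (TP + TN) / (TP + FN + TN + FP)
    PPV = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

PPV is undefined (reported as missing, not zero) when no positive
prediction was made; MCC with a zero factor in the denominator is
reported as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .alert_filtering import AlertSet, FilterConfig, apply_filter
from .chem_io import MoleculeRecord, ToxicityDataset
from .fragment_mining import build_table, compile_query


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RepetitionResult:
    """Metrics for one train/test repetition of the holdout protocol."""

    seed: int
    n_alerts: int
    train_confusion: ConfusionCounts | None
    test_confusion: ConfusionCounts | None
    train_metrics: dict[str, float | None]
    test_metrics: dict[str, float | None]
    failed: bool = False
    failure_reason: str | None = None


@dataclass
class EvaluationReport:
    """Per-repetition results plus means over the successful repetitions.

    Means of PPV skip missing values (no positive predictions) and record
    how many repetitions contributed.
    """

    endpoint: str
    strategy: str
    per_rep: list[RepetitionResult] = field(default_factory=list)
    failed: bool = False

    def _mean(self, split: str, metric: str) -> tuple[float | None, int]:
        values = [
            getattr(r, f"{split}_metrics")[metric]
            for r in self.per_rep
            if not r.failed and getattr(r, f"{split}_metrics")[metric] is not None
        ]
        if not values:
            return None, 0
        return float(np.mean(values)), len(values)

    def means(self) -> dict[str, dict[str, float | None]]:
        out: dict[str, dict[str, float | None]] = {}
        for split in ("train", "test"):
            out[split] = {}
            for metric in ("acc", "ppv", "mcc"):
                mean, n = self._mean(split, metric)
                out[split][metric] = mean
                out[split][f"{metric}_n"] = n
        return out


def predict(alerts: AlertSet, mol: MoleculeRecord | Chem.Mol | str) -> int:
    """1 iff the molecule contains at least one alert pattern (no vote counting)."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol()
    elif isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    for alert in alerts.alerts:
        is_smarts = alert.key.origin == "catalogue"
        if mol.HasSubstructMatch(compile_query(alert.key.pattern, smarts=is_smarts)):
            return 1
    return 0


def confusion(alerts: AlertSet, dataset: ToxicityDataset) -> ConfusionCounts:
    if dataset.n_total == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    tp = fp = tn = fn = 0
    for rec in dataset.records:
        pred = predict(alerts, rec)
        if pred == 1 and rec.label == 1:
            tp += 1
        elif pred == 1 and rec.label == 0:
            fp += 1
        elif pred == 0 and rec.label == 0:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, PPV and MCC from a confusion matrix, with degenerate-case conventions."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.total
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return {"acc": acc, "ppv": ppv, "mcc": mcc}


def split_indices(
    n: int, seed: int, train_frac: float = 0.8, labels: Sequence[int] | None = None,
    stratified: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic random train/test split: floor(n*train_frac) train, rest test."""
    rng = np.random.default_rng(seed)
    if stratified and labels is not None:
        labels = np.asarray(labels)
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            cut = int(math.floor(len(idx) * train_frac))
            train_parts.append(idx[:cut])
            test_parts.append(idx[cut:])
        return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))
    perm = rng.permutation(n)
    cut = int(math.floor(n * train_frac))
    return np.sort(perm[:cut]), np.sort(perm[cut:])


Miner = Callable[[ToxicityDataset], AlertSet]


def make_miner(
    strategy: str,
    strategy_params: dict | None = None,
    config: FilterConfig | None = None,
    catalogue=None,
) -> Miner:
    """Bundle a mining strategy + filter configuration into a dataset -> AlertSet callable."""

    def miner(dataset: ToxicityDataset) -> AlertSet:
        table = build_table(dataset, strategy, strategy_params, catalogue=catalogue)
        return apply_filter(table, dataset, config)

    return miner


def repeated_holdout(
    dataset: ToxicityDataset,
    miner: Miner,
    n_reps: int = 5,
    train_frac: float = 0.8,
    seeds: Sequence[int] | None = None,
    stratified: bool = False,
    strategy: str = "",
) -> EvaluationReport:
    """The 8:2 x 5 holdout protocol: mine on train, evaluate on train and test.

    Alerts are always re-mined from the training split alone, so test
    molecules never influence the alert set. Repetitions where mining
    fails (no qualifying alert) are recorded and excluded from means.
    """
    seeds = list(seeds) if seeds is not None else list(range(1, n_reps + 1))
    if len(seeds) != n_reps:
        raise ValueError(f"need {n_reps} seeds, got {len(seeds)}")
    labels = [r.label for r in dataset.records]
    report = EvaluationReport(endpoint=dataset.endpoint, strategy=strategy)
    for seed in seeds:
        train_idx, test_idx = split_indices(
            dataset.n_total, seed, train_frac, labels=labels, stratified=stratified
        )
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        alerts = miner(train)
        if not report.strategy and alerts.strategy:
            report.strategy = alerts.strategy
        if alerts.failed:
            warnings.warn(
                f"repetition seed={seed}: mining failed ({alerts.failure}); excluded from means",
                stacklevel=2,
            )
            report.per_rep.append(
                RepetitionResult(
                    seed=seed,
                    n_alerts=0,
                    train_confusion=None,
                    test_confusion=None,
                    train_metrics={"acc": None, "ppv": None, "mcc": None},
                    test_metrics={"acc": None, "ppv": None, "mcc": None},
                    failed=True,
                    failure_reason=alerts.failure,
                )
            )
            continue
        c_train = confusion(alerts, train)
        c_test = confusion(alerts, test)
        report.per_rep.append(
            RepetitionResult(
                seed=seed,
                n_alerts=len(alerts),
                train_confusion=c_train,
                test_confusion=c_test,
                train_metrics=metrics(c_train),
                test_metrics=metrics(c_test),
            )
        )
    report.failed = all(r.failed for r in report.per_rep)
    return report
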