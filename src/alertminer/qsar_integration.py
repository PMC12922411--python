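"""Fingerprint random-forest QSAR model and the alert-conjunction rule.

The integrated predictor labels a compound toxic only when the QSAR score
exceeds the threshold (strictly) AND the compound contains at least one
structural alert. Its positive-prediction set is therefore exactly the
intersection of the two components' positive sets: the conjunction can
remove false positives of the score-only model but never add one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier

from .alert_filtering import AlertSet
from .chem_io import MoleculeRecord, ToxicityDataset
from .sa_classifier import (
    ConfusionCounts,
    Miner,
    metrics,
    predict,
    split_indices,
)

_FP_GENERATORS: dict[int, object] = {}


def _generator(n_bits: int):
    if n_bits not in _FP_GENERATORS:
        _FP_GENERATORS[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=n_bits
        )
    return _FP_GENERATORS[n_bits]


def featurize(mol: MoleculeRecord | Chem.Mol | str, n_bits: int = 2048) -> np.ndarray:
    """Binary circular fingerprint of radius 2 (ECFP4-equivalent), deterministic."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol()
    elif isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    if mol.GetNumAtoms() == 0:
        raise ValueError("cannot featurize an empty molecule")
    fp = _generator(n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def featurize_dataset(dataset: ToxicityDataset, n_bits: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([featurize(r, n_bits) for r in dataset.records])
    y = np.array([r.label for r in dataset.records], dtype=int)
    return X, y


def train_qsar(
    train: ToxicityDataset,
    seed: int = 0,
    n_trees: int = 500,
    n_bits: int = 2048,
) -> RandomForestClassifier:
    """Fit a random forest on circular fingerprints; reproducible given the seed."""
    X, y = featurize_dataset(train, n_bits)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; cannot fit a classifier")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return clf


def qsar_scores(clf: RandomForestClassifier, dataset: ToxicityDataset, n_bits: int = 2048) -> np.ndarray:
    """Probability of the toxic class for every record, in [0, 1]."""
    X, _ = featurize_dataset(dataset, n_bits)
    positive_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(X)[:, positive_col]


@dataclass
class IntegratedModel:
    """A trained QSAR classifier plus an alert set mined on the same training split."""

    qsar: RandomForestClassifier
    alerts: AlertSet
    threshold: float = 0.5
    n_bits: int = 2048
    seed: int = 0


def integrated_predict(model: IntegratedModel, mol: MoleculeRecord | str) -> int:
    """1 iff QSAR score strictly exceeds the threshold AND an alert is present."""
    if isinstance(mol, MoleculeRecord):
        rec = mol
    else:
        rec = MoleculeRecord(id="query", smiles=mol, label=0)
    single = ToxicityDataset(endpoint="query", records=[rec])
    score = float(qsar_scores(model.qsar, single, model.n_bits)[0])
    return int(score > model.threshold and predict(model.alerts, rec) == 1)


def _confusion_from_vectors(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class ModelComparison:
    """Test-split metrics for QSAR-alone, alerts-alone and the integrated rule."""

    endpoint: str
    seed: int
    n_test: int
    n_alerts: int
    qsar: dict[str, float | None]
    alerts: dict[str, float | None]
    integrated: dict[str, float | None]
    qsar_confusion: ConfusionCounts
    alerts_confusion: ConfusionCounts
    integrated_confusion: ConfusionCounts
    mining_failed: bool = False


def compare_models(
    dataset: ToxicityDataset,
    miner: Miner,
    seed: int = 1,
    train_frac: float = 0.8,
    threshold: float = 0.5,
    n_trees: int = 500,
    n_bits: int = 2048,
) -> ModelComparison:
    """Train QSAR and mine alerts on one 8:2 split; score all three models on its test set.

    All three predictors share the identical split, so their metrics are
    directly comparable. If mining fails, the alert and integrated
    predictions degenerate to all-negative (the comparison is still
    reported, flagged).
    """
    train_idx, test_idx = split_indices(dataset.n_total, seed, train_frac)
    train = dataset.subset(train_idx)
    test = dataset.subset(test_idx)
    clf = train_qsar(train, seed=seed, n_trees=n_trees, n_bits=n_bits)
    alerts = miner(train)
    scores = qsar_scores(clf, test, n_bits)
    y_true = np.array([r.label for r in test.records], dtype=int)
    y_qsar = (scores > threshold).astype(int)
    y_alerts = np.array([predict(alerts, r) for r in test.records], dtype=int)
    y_int = y_qsar & y_alerts
    c_qsar = _confusion_from_vectors(y_true, y_qsar)
    c_alerts = _confusion_from_vectors(y_true, y_alerts)
    c_int = _confusion_from_vectors(y_true, y_int)
    return ModelComparison(
        endpoint=dataset.endpoint,
        seed=seed,
        n_test=test.n_total,
        n_alerts=len(alerts),
        qsar=metrics(c_qsar),
        alerts=metrics(c_alerts),
        integrated=metrics(c_int),
        qsar_confusion=c_qsar,
        alerts_confusion=c_alerts,
        integrated_confusion=c_int,
        mining_failed=alerts.failed,
    )
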