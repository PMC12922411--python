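"""Per-substructure statistics: precision, coverage rate and information gain.

For a substructure with support counts (N_sub, N_sub-positive) on a dataset
of N_total compounds of which N_positive are toxic:

    PR = N_sub-positive / N_sub
    CR = N_sub / N_total
    IG = E(p_all) - P(t) * E(p|t) - P(t-bar) * E(p|t-bar)

where E(p) = -p*log2(p) - (1-p)*log2(1-p) is the binary entropy of the
positive-class probability and t is the event "compound contains the
substructure". IG is the entropy reduction achieved by partitioning the
dataset on substructure presence; alerts with both high PR and high CR
carry the most information and rank highest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chem_io import ToxicityDataset
from .fragment_mining import AlertSupport, FragmentKey


@dataclass(frozen=True)
class ScoredAlert:
    """A fragment with its support counts and PR/CR/IG/p-value statistics."""

    key: FragmentKey
    support: AlertSupport
    pr: float
    cr: float
    ig: float
    p_value: float


def precision(support: AlertSupport) -> float:
    """Fraction of substructure-bearing compounds that are toxic."""
    if support.n_sub < 1:
        raise ValueError("precision undefined for n_sub = 0")
    return support.n_sub_positive / support.n_sub


def coverage(support: AlertSupport, dataset: ToxicityDataset) -> float:
    """Fraction of the dataset bearing the substructure."""
    if dataset.n_total < 1:
        raise ValueError("coverage undefined on an empty dataset")
    return support.n_sub / dataset.n_total


def entropy(p: float, base: float = 2.0) -> float:
    """Binary entropy of a class probability, with 0*log(0) = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    if p in (0.0, 1.0):
        return 0.0
    log = (lambda x: math.log(x, base)) if base != 2.0 else math.log2
    return -p * log(p) - (1.0 - p) * log(1.0 - p)


def information_gain(
    support: AlertSupport, dataset: ToxicityDataset, base: float = 2.0
) -> float:
    """Entropy reduction from partitioning the dataset on substructure presence.

    Negative floating-point dust is clamped to zero; the result is bounded
    above by the total entropy of the label distribution.
    """
    n_total, n_positive = dataset.n_total, dataset.n_positive
    if n_total < 1:
        raise ValueError("dataset is empty")
    if support.n_sub > n_total or support.n_sub_positive > n_positive:
        raise ValueError(
            f"support {support} inconsistent with dataset "
            f"(n_total={n_total}, n_positive={n_positive})"
        )
    if (support.n_sub - support.n_sub_positive) > (n_total - n_positive):
        raise ValueError(f"support {support} implies more negatives than the dataset holds")
    p_all = n_positive / n_total
    p_t = support.n_sub / n_total
    p_match = support.n_sub_positive / support.n_sub if support.n_sub else 0.0
    rest = n_total - support.n_sub
    p_nomatch = (n_positive - support.n_sub_positive) / rest if rest else 0.0
    ig = (
        entropy(p_all, base)
        - p_t * entropy(p_match, base)
        - (1.0 - p_t) * entropy(p_nomatch, base)
    )
    return max(ig, 0.0)


def score_alert(
    key: FragmentKey,
    support: AlertSupport,
    dataset: ToxicityDataset,
    p_value: float = float("nan"),
) -> ScoredAlert:
    return ScoredAlert(
        key=key,
        support=support,
        pr=precision(support),
        cr=coverage(support, dataset),
        ig=information_gain(support, dataset),
        p_value=p_value,
    )


def rank_top_k(alerts: list[ScoredAlert], k: int) -> list[ScoredAlert]:
    """Top-k alerts by IG, descending; deterministic tie-break chain.

    Ties on IG fall back to higher PR, then higher CR, then lexicographic
    pattern, so the ranking is invariant to input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(alerts, key=lambda a: (-a.ig, -a.pr, -a.cr, a.key.pattern))
    return ordered[:k]
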