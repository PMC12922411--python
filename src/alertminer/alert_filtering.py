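"""Statistical filtering of candidate fragments into qualified alert sets.

Two modes mirror the two filtering philosophies of the mining tools this
package reimplements:

* ``significance`` — keep fragments with enough hits (minNum), enough
  precision (minACC) and a Bonferroni-adjusted one-sided binomial p-value
  below alpha, testing enrichment of positives among fragment bearers
  against the dataset base rate.
* ``support`` — keep fragments frequent in the positive (focus) class and
  rare in the negative (complement) class, the closed-subgraph miners'
  focus/complement support filter.

An extraction that retains nothing is a reportable outcome (the dataset
"does not tolerate" the method at these thresholds), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import binom

from .alert_scoring import ScoredAlert, precision, score_alert
from .chem_io import ToxicityDataset
from .fragment_mining import AlertSupport, FragmentTable


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds controlling which fragments qualify as alerts.

    Defaults are the uniform running parameters used across strategies:
    minNum = 5, minACC = 0.75, alpha = 0.05 with Bonferroni correction.
    ``min_frequency`` is an optional extra dataset-frequency floor
    (n_sub / n_total) used in catalogue mode.
    """

    min_hits: int = 5
    min_precision: float = 0.75
    alpha: float = 0.05
    bonferroni: bool = True
    mode: str = "significance"
    focus_support_min: float = 0.10
    complement_support_max: float = 0.05
    min_frequency: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_precision <= 1.0:
            raise ValueError("min_precision must be in (0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 < self.focus_support_min <= 1.0:
            raise ValueError("focus_support_min must be in (0, 1]")
        if not 0.0 < self.complement_support_max <= 1.0:
            raise ValueError("complement_support_max must be in (0, 1]")
        if self.mode not in ("significance", "support"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass
class AlertSet:
    """A named collection of qualified, scored alerts for one (endpoint, strategy).

    ``failure`` carries the reason when zero alerts qualified, mirroring the
    tolerance bookkeeping of mining-tool comparisons.
    """

    endpoint: str
    strategy: str
    alerts: list[ScoredAlert] = field(default_factory=list)
    config: FilterConfig | None = None
    failure: str | None = None

    def __len__(self) -> int:
        return len(self.alerts)

    @property
    def failed(self) -> bool:
        return self.failure is not None


def fragment_pvalue(support: AlertSupport, dataset: ToxicityDataset) -> float:
    """One-sided exact binomial tail P(X >= n_sub_positive | n_sub, base rate).

    Tests whether positives are enriched among compounds bearing the
    fragment, relative to the dataset's positive fraction.
    """
    if dataset.n_total == 0:
        raise ValueError("dataset is empty")
    if support.n_sub < 1:
        raise ValueError("p-value undefined for n_sub = 0")
    p0 = dataset.n_positive / dataset.n_total
    # sf(k-1) = P(X >= k)
    return float(binom.sf(support.n_sub_positive - 1, support.n_sub, p0))


def apply_filter(
    table: FragmentTable, dataset: ToxicityDataset, config: FilterConfig | None = None
) -> AlertSet:
    """Reduce a fragment table to the alerts passing every active threshold.

    In significance mode the Bonferroni multiplicity m counts only the
    fragments that reached ``min_hits`` — fragments below the hit floor were
    never candidate hypotheses. The adjusted p-value is min(1, p*m).
    """
    config = config or FilterConfig()
    strategy = next(iter(table.rows)).origin if table.rows else ""
    kept: list[ScoredAlert] = []
    if config.mode == "significance":
        candidates = [
            (key, sup) for key, sup in table.rows.items() if sup.n_sub >= config.min_hits
        ]
        m = len(candidates)
        for key, sup in candidates:
            if precision(sup) < config.min_precision:
                continue
            if config.min_frequency and sup.n_sub / dataset.n_total < config.min_frequency:
                continue
            p = fragment_pvalue(sup, dataset)
            p_adj = min(1.0, p * m) if config.bonferroni else p
            if p_adj <= config.alpha:
                kept.append(score_alert(key, sup, dataset, p_value=p_adj))
    else:  # support mode (focus/complement)
        n_pos, n_neg = dataset.n_positive, dataset.n_negative
        for key, sup in table.rows.items():
            focus = sup.n_sub_positive / n_pos if n_pos else 0.0
            complement = (sup.n_sub - sup.n_sub_positive) / n_neg if n_neg else 0.0
            if focus >= config.focus_support_min and complement <= config.complement_support_max:
                p = fragment_pvalue(sup, dataset) if sup.n_sub >= 1 else 1.0
                kept.append(score_alert(key, sup, dataset, p_value=p))
    kept.sort(key=lambda a: (-a.ig, -a.pr, -a.cr, a.key.pattern))
    result = AlertSet(
        endpoint=dataset.endpoint, strategy=strategy, alerts=kept, config=config
    )
    if not kept:
        result.failure = (
            f"no fragment satisfied the {config.mode}-mode thresholds "
            f"(min_hits={config.min_hits}, min_precision={config.min_precision})"
        )
    return result


def screen_external(
    alerts: AlertSet, min_hits: int = 5, min_precision: float = 0.75
) -> AlertSet:
    """Post-hoc screen applied to rule sets mined under non-uniform constraints.

    Keeps alerts with n_sub >= min_hits and PR >= min_precision (both bounds
    inclusive), preserving order. An empty result here is not a failure —
    the screen is a comparability step, not an extraction.
    """
    kept = [
        a
        for a in alerts.alerts
        if a.support.n_sub >= min_hits and a.pr >= min_precision
    ]
    return replace_alerts(alerts, kept)


def replace_alerts(alerts: AlertSet, new_alerts: list[ScoredAlert]) -> AlertSet:
    return AlertSet(
        endpoint=alerts.endpoint,
        strategy=alerts.strategy,
        alerts=list(new_alerts),
        config=alerts.config,
        failure=None,
    )
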