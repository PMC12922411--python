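"""Run manifests and the tolerance/count summary tables.

Each mining invocation appends one manifest entry recording the endpoint,
strategy, outcome (ok / failed with reason) and alert count.
``summarize_run`` turns a list of manifests into the endpoint-by-strategy
count table with failures marked, plus a per-strategy failure tally — the
bookkeeping used to compare how well each strategy tolerates different
datasets.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class ManifestEntry:
    endpoint: str
    strategy: str
    outcome: str  # "ok" or "failed: <reason>"
    n_alerts: int
    seconds: float | None = None

    @property
    def failed(self) -> bool:
        return self.outcome.startswith("failed")


@dataclass
class RunManifest:
    """Append-only record of every mining invocation in a run."""

    config: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)
    entries: list[ManifestEntry] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, endpoint: str, strategy: str, alerts, seconds: float | None = None) -> None:
        outcome = f"failed: {alerts.failure}" if alerts.failed else "ok"
        self.entries.append(
            ManifestEntry(
                endpoint=endpoint,
                strategy=strategy,
                outcome=outcome,
                n_alerts=len(alerts),
                seconds=seconds,
            )
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def summarize_run(manifests: list[RunManifest]) -> tuple[pd.DataFrame, pd.Series]:
    """Alert-count table (endpoint x strategy, failures marked) + failure tally.

    Cells hold the alert count as a string, or ``"FAILED"`` for extractions
    that retained nothing. All-failure runs still summarize cleanly —
    reporting is never an error.
    """
    if not manifests:
        raise ValueError("need at least one manifest")
    entries = [e for m in manifests for e in m.entries]
    if not entries:
        raise ValueError("manifests contain no mining invocations")
    records = [
        {
            "endpoint": e.endpoint,
            "strategy": e.strategy,
            "cell": "FAILED" if e.failed else str(e.n_alerts),
            "failed": e.failed,
        }
        for e in entries
    ]
    df = pd.DataFrame(records)
    counts = df.pivot_table(
        index="endpoint", columns="strategy", values="cell", aggfunc="first"
    )
    failures = df.groupby("strategy")["failed"].sum().astype(int)
    return counts, failures
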