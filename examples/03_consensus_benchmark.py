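"""Build a consensus benchmark alert set across mining strategies.

Mines the same endpoint with three strategies, normalizes every pattern to
canonical SMILES, consolidates inclusion-related patterns to the simpler
form, drops strategies with fewer than the minimum number of alerts and
intersects the rest. Also prints the pairwise overlap matrix.
"""

from alertminer import build_benchmark, make_miner, pairwise_overlap
from alertminer.synthetic_data import SyntheticSpec, generate

syn = generate(SyntheticSpec(seed=1))
sets = {}
for strategy in ("circular", "path", "bondbreak"):
    alerts = make_miner(strategy)(syn.dataset)
    sets[strategy] = alerts
    print(f"{strategy:<10} {len(alerts):>4} alerts (failed: {alerts.failed})")

result = build_benchmark(sets, min_set_size=5)
print(f"\nincluded strategies: {result.included_strategies}")
print(f"excluded (too few alerts): {result.excluded_strategies}")
print(f"benchmark ({len(result.benchmark)} patterns shared by all included):")
for a in result.benchmark[:10]:
    print(f"  {a.canonical:<30} sources={sorted(a.sources)}")

matrix, strategies = pairwise_overlap(sets)
print(f"\npairwise identical-alert counts {strategies}:")
print(matrix)
# the diagonal holds each strategy's consolidated set size; off-diagonal
# cells count normalized patterns two strategies share.
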