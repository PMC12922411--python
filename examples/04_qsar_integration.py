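"""Combine a fingerprint random-forest model with structural alerts.

Trains an ECFP4-style random forest and mines alerts on the same 8:2
training split, then compares three predictors on the held-out test set:
the score-only model (score > 0.5), the alerts-only rule model, and the
integrated rule (score > 0.5 AND an alert present).
"""

from alertminer import compare_models, make_miner
from alertminer.synthetic_data import SyntheticSpec, generate

syn = generate(SyntheticSpec(seed=1))
result = compare_models(syn.dataset, make_miner("circular"), seed=1)

print(f"test set: {result.n_test} molecules; {result.n_alerts} alerts mined on train\n")
print(f"{'model':<12} {'ACC':>7} {'PPV':>7} {'MCC':>7} {'FP':>4}")
for name, m, c in [
    ("QSAR", result.qsar, result.qsar_confusion),
    ("alerts", result.alerts, result.alerts_confusion),
    ("integrated", result.integrated, result.integrated_confusion),
]:
    ppv = f"{m['ppv']:.3f}" if m["ppv"] is not None else "  n/a"
    print(f"{name:<12} {m['acc']:>7.3f} {ppv:>7} {m['mcc']:>7.3f} {c.fp:>4}")

# the integrated rule predicts positive only where both components agree,
# so its false-positive count can never exceed either component's.
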