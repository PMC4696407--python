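"""ROC analysis, optimal thresholds and model comparison on PIS scores.

Scores the benchmark's holdout half with a trained cascade, analyses both
dichotomizations of the graded outcome (any inhibition vs none; multi-P450
vs not) and compares the cascade against a deliberately degraded score
vector with the paired DeLong test.
"""

import numpy as np

from p450nnc import (
    DescriptorMatrix,
    SyntheticSpec,
    auroc,
    compare_auroc,
    dichotomize,
    generate_qsar,
    predict_pis,
    spearman,
    train_benchmark_cascade,
    youden_threshold,
)

dataset = generate_qsar(SyntheticSpec(seed=1))
model = train_benchmark_cascade(dataset)
hold = dataset.holdout_idx
pis = predict_pis(model, DescriptorMatrix(dataset.matrix.frame.iloc[hold]))
counts = dataset.counts[hold]

res = spearman(pis, counts)
print(f"Spearman rho(PIS, inhibited-isoform count) = {res.statistic:.3f} (p = {res.p_value:.2e})")

for task, label in [("inhibitor_task", "inhibitor vs non-inhibitor"),
                    ("multi_task", "multi-P450 vs non-multi")]:
    y = dichotomize(counts, task)
    roc = auroc(pis, y, task)
    t = youden_threshold(roc)
    acc = np.mean((pis > t).astype(int) == y)
    print(f"{label}: AUROC={roc.auroc:.3f}, optimal PIS threshold={t:.4f}, "
          f"accuracy at threshold={acc:.3f}")

# paired comparison: the cascade's PIS vs a noise-degraded copy
rng = np.random.default_rng(0)
degraded = np.clip(pis + rng.normal(0, 0.2, pis.size), 0, 1)
y = dichotomize(counts, "multi_task")
cmp = compare_auroc(pis, degraded, y)
print(f"\nDeLong paired test, PIS vs degraded PIS (multi task): "
      f"z={cmp.statistic:.2f}, p={cmp.p_value:.2e}")
print("A small p-value says the two ROC curves differ beyond what their shared")
print("compounds can explain; the cascade's AUROC is genuinely higher.")
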