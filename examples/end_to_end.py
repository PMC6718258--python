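"""Full caller pipeline on a synthetic cohort: simulate panel VCFs, extract
per-locus indel features, train the k = 3 centroid model, classify a fresh
cohort and summarize diagnostic performance.

Run:  python examples/end_to_end.py
"""

import tempfile
from pathlib import Path

from msikit import (
    SimParams,
    classify_cohort,
    cohort_feature_matrix,
    confusion,
    performance,
    simulate_cohort,
    train_kmeans,
)

with tempfile.TemporaryDirectory() as tmp:
    params = SimParams()

    # Training cohort mirroring the assay's development set:
    # 22 MSI-H tumors, 25 MSS tumors, 47 normal tissues.
    train_sim = simulate_cohort(params, 22, 25, 47, Path(tmp) / "train", seed=17)
    fm = cohort_feature_matrix(train_sim)
    print(f"feature matrix: {fm.values.shape[0]} samples x {fm.values.shape[1]} features")

    labels = [train_sim.truth[s] for s in fm.sample_ids]
    model = train_kmeans(fm, labels, seed=0)
    print(f"cluster labels after majority naming: {model.cluster_labels}")

    # Classify an independently simulated cohort of the same composition.
    held_sim = simulate_cohort(params, 22, 25, 47, Path(tmp) / "held", seed=1017)
    calls = classify_cohort(cohort_feature_matrix(held_sim), model)

    counts = confusion({c.sample_id: c.label for c in calls}, held_sim.truth)
    perf = performance(counts)
    print(f"confusion: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn} "
          f"inconclusive={counts.inconclusive} of {counts.total}")
    print("metrics over conclusive calls:", perf.percent_summary())

# The confusion row mirrors the assay's validation layout: inconclusive
# samples (|D| < 3) are withheld from the error cells, so sensitivity,
# specificity, PPV, NPV and accuracy describe conclusive calls only.
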