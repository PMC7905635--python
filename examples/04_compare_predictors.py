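"""Compare two predictors with McNemar's paired test.

A trained forest is compared against a degenerate baseline that calls
every ORF coding. The baseline keeps sensitivity perfect but its
specificity collapses; McNemar's test on the paired per-ORF correctness
shows the difference is systematic, not sampling noise.
"""

import pandas as pd

from orfrf import classifier, evaluation, labeling, synthetic
from orfrf.features import FEATURE_NAMES
from orfrf.orfs import extract_orfs
from orfrf.seqio import GenomeAnnotation


def dataset(seed: int, cap: int):
    cs = synthetic.CommunitySpec(
        n_genomes=4, base=synthetic.GenomeSpec(n_genes=120), seed=seed
    )
    ann = GenomeAnnotation()
    orfs = []
    for rec, a in synthetic.generate_community(cs):
        orfs.extend(extract_orfs(rec))
        ann.add_seqid(rec.id)
        for sid in a.seqids():
            for iv in a.intervals(sid):
                ann.add(iv)
    return labeling.build_dataset(orfs, ann, seed=seed, max_per_class=cap)


model, _ = classifier.train(
    dataset(seed=5, cap=200),
    classifier.TrainingConfig(mtry_grid=(3,), cv_repeats=2, seed=0),
)
test_set = dataset(seed=6, cap=150)
X = pd.DataFrame([i.features.as_array() for i in test_set], columns=list(FEATURE_NAMES))
truth = [i.label for i in test_set]
rf_labels = [p.label for p in classifier.predict(model, X)]
baseline_labels = ["coding"] * len(truth)

for name, labels in [("random forest", rf_labels), ("always-coding", baseline_labels)]:
    cc = evaluation.confusion(labels, truth)
    print(
        f"{name:>14}: accuracy {evaluation.accuracy(cc):.3f}, "
        f"sensitivity {evaluation.sensitivity(cc):.3f}, "
        f"specificity {evaluation.specificity(cc):.3f}"
    )

rf_correct = [p == t for p, t in zip(rf_labels, truth)]
base_correct = [p == t for p, t in zip(baseline_labels, truth)]
res = evaluation.mcnemar(rf_correct, base_correct, alpha=0.01)
print("\npaired contingency (correct/wrong):")
print(evaluation.contingency_table(rf_correct, base_correct))
stat = "exact binomial" if res.exact else f"chi2 = {res.statistic:.3f}"
print(
    f"\nMcNemar: b={res.b}, c={res.c}, {stat}, p = {res.p_value:.3g} "
    f"-> {'significant' if res.significant else 'not significant'} at alpha 0.01"
)
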