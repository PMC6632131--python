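"""Diagnostic evaluation with stage and control-cohort subgroups.

Simulates a validation-style cohort in which the planted effect grows
with tumor stage, scores every sample with a discriminant fit on a
training cohort from the same panel, and reports sensitivity by stage,
specificity by control source, and the overall ROC AUC with its DeLong
confidence interval — the standard read-out of a diagnostic index.
"""

from ecindex import (
    SimulationConfig,
    evaluate_scores,
    fit_fisher_lda,
    normalize_internal_controls,
    positive_call_subtract,
    simulate_cohort,
)
from ecindex.preprocess import freeze_reference

cfg = SimulationConfig(
    n_case=120, n_control=120, n_mirna=60, n_differential=3, effect_size=1.6,
    stage_distribution={"0": 0.12, "I": 0.3, "II": 0.23, "III": 0.2, "IV": 0.15},
    effect_by_stage={"0": 0.4, "I": 0.7, "II": 1.0, "III": 1.3, "IV": 1.6},
    seed=8,
)
train, truth = simulate_cohort(cfg)
valid, _ = simulate_cohort(cfg, sample_seed=999)  # independent, same panel

sub = positive_call_subtract(train)
norm = normalize_internal_controls(sub)
model = fit_fisher_lda(
    norm.feature_matrix(truth.differential_mirna_ids),
    train.group_labels,
    feature_names=truth.differential_mirna_ids,
)

frozen = freeze_reference(sub)  # normalize new arrays onto the training scale
vnorm = normalize_internal_controls(positive_call_subtract(valid), frozen)
scores = model.score_matrix(vnorm.feature_matrix(model.mirna_ids))

report = evaluate_scores(scores, valid.group_labels, meta=valid.samples)
s, sp, a = report.metrics.sensitivity, report.metrics.specificity, report.auc
print(f"overall: sensitivity {s.value:.2f} ({s.ci_low:.2f}-{s.ci_high:.2f}), "
      f"specificity {sp.value:.2f} ({sp.ci_low:.2f}-{sp.ci_high:.2f}), "
      f"AUC {a.auc:.2f} ({a.ci_low:.2f}-{a.ci_high:.2f})")
print("sensitivity by stage (planted effect grows with stage):")
for stage, m in report.by_stage.items():
    print(f"  stage {stage:>3s}: {m.value:.2f}  (n={m.n})")
print("specificity by control cohort:")
for src, m in report.by_control_source.items():
    print(f"  {src}: {m.value:.2f}  (n={m.n})")
print("Early stages carry a weaker planted shift, so their sensitivity is "
      "lower — the pattern real stage-stratified validation reports show.")
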