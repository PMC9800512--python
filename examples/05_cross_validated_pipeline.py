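"""Cross-validated wrapper-selection experiment on a synthetic cohort.

Runs the full per-fold pipeline (binary SBCS feature search on the
training partition, KELM on the selected columns, held-out scoring)
over 2 x 5-fold stratified CV at a small search budget and prints the
metric summary and the feature-selection frequency table.
"""

from sbcskelm import CVPlan, OptimizerSettings, run_cv_experiment, planted_signal_cohort

cohort, _ = planted_signal_cohort(n_per_group=50, effect_size=1.5, seed=2)
X = cohort.drop(columns="risk_group")
y = cohort["risk_group"].to_numpy()

result = run_cv_experiment(
    X,
    y,
    optimizer_settings=OptimizerSettings(population_size=10, max_evaluations=300),
    plan=CVPlan(k=5, repeats=2, seed=2),
    positive_class="high",
)

print("metric summary over 10 folds:")
print(result.summary.to_string())
print("\nmost frequently selected features:")
print(result.feature_counts.sort_values(ascending=False).head(8).to_string())
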