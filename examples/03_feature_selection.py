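"""Wrapper feature selection with the binary SBCS-KELM pipeline.

Builds a cohort with five planted informative features among 23, runs
the sigmoid-transfer binary search scored by an inner 5-fold KELM
error, and prints the selected subset with its fitness
(0.99 * error + 0.01 * subset fraction).
"""

from sbcskelm import FSProblem, OptimizerSettings, planted_signal_cohort, run_binary_fs

cohort, truth = planted_signal_cohort(effect_size=1.0, seed=4)
X = cohort.drop(columns="risk_group")
y = cohort["risk_group"]

problem = FSProblem(X, y, seed=4)
settings = OptimizerSettings(
    population_size=20, max_evaluations=2000, variant="SBCS", seed=4
)
result = run_binary_fs(problem, settings)

print(f"selected {result.mask.selected_count} of {problem.n_features} features")
print(f"fitness {result.fitness:.4f}, inner CV error {result.inner_error:.4f}")
print("selected:", ", ".join(result.selected_names()))
planted = [n for n, t in zip(problem.feature_names, truth) if t]
recovered = set(result.selected_names()) & set(planted)
print(f"planted features recovered: {len(recovered)}/{len(planted)} ({sorted(recovered)})")
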