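"""Factorial comparison of search variants on the classic suite.

Runs CS and SBCS on three functions over 6 seeds each, then prints the
mean final fitness table, the pairwise Wilcoxon verdicts against the
reference ('+' means the reference is significantly lower) and the
Friedman mean ranks.
"""

from sbcskelm import OptimizerSettings, classic_suite, run_benchmark

suite = classic_suite(dim=10, names=["sphere", "rastrigin", "ackley"])
settings = OptimizerSettings(population_size=30, max_evaluations=5000, seed=0)
result = run_benchmark(["CS", "SBCS"], suite, settings, seeds=6)

print("mean final fitness:")
print(result.avg.to_string())
print(f"\nWilcoxon verdicts (reference: {result.reference}):")
print(result.wilcoxon.to_string())
print("\nFriedman mean ranks (lower is better):")
print(result.friedman.to_string())
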