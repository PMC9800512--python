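"""Minimise a classic benchmark function with each search variant.

Runs the four cuckoo-search variants on the 10-dimensional Rastrigin
function under the same evaluation budget and prints the best value
each one reaches — the Sobol-initialised, wormhole-augmented variant
(SBCS) typically finishes lowest.
"""

from sbcskelm import OptimizerSettings, classic_suite, run_optimizer

fn = classic_suite(dim=10)["rastrigin"]

for variant in ("CS", "SCS", "BCS", "SBCS"):
    settings = OptimizerSettings(
        population_size=30, max_evaluations=10_000, variant=variant, seed=1
    )
    best, trace = run_optimizer(fn.objective, fn.space, settings)
    print(f"{variant:>4s}: best fitness {best.fitness:10.4f} "
          f"after {trace.evaluations_used[-1]} evaluations")
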