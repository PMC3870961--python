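"""Validate the whole pipeline on simulated data with known architecture.

Generates a 200-gene panel, quantifies, calls linkage with Welch tests, and
scores the inferred linkage sets against the simulator's ground truth.
"""

from flylinkage import ArchitecturePriors, Scenario, run_recovery_experiment

priors = ArchitecturePriors(effect_low=1.5, effect_high=1.5)
scenario = Scenario(n_genes=200, noise_sd=0.15, seed=1, priors=priors)
report, calls, specs = run_recovery_experiment(scenario)

print(f"exact factor-set recovery: {100 * report.exact_set_fraction:.1f}% of 200 genes")
print(f"edge-level sensitivity:    {report.edge_sensitivity:.3f}")
print(f"edge-level FDP:            {report.edge_fdp:.3f}")
print("\nper-autosome sensitivity:", {a: round(v, 2) for a, v in report.per_autosome_sensitivity.items()})
# With triplicates, 0.15 log2 replicate noise and 1.5 log2 effects, nearly
# every true factor edge is detected; the residual inexact sets come from
# the ~3-4% per-line false-positive rate of the unadjusted Welch calls.
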