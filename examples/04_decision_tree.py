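"""Rank baseline discriminants of the response clusters with CART.

Fits the from-scratch Gini decision tree on baseline covariates of a
synthetic cohort against the Ward cluster labels and prints the
normalized feature-importance ranking — the package's analogue of the
"main discriminants" analysis.
"""

from phenoresp import (
    PipelineConfig,
    SimulationConfig,
    run_all,
    simulate_cohort,
    write_cohort,
)

config = SimulationConfig(seed=7)
cohort = simulate_cohort(config)
paths = write_cohort(cohort, config, "scratch/example_cohort")

result = run_all(PipelineConfig(visits_csv=str(paths["visits"]),
                                baseline_csv=str(paths["baselines"]),
                                out_dir="scratch/example_run", seed=7))

print(f"training accuracy on {result['manifest']['n_clustered']} patients "
      f"(descriptive fit, chance = 0.25): "
      f"{result['manifest']['training_accuracy']:.2f}\n")
print("top baseline discriminants (normalized Gini importance):")
print(result["importance"].head(8).round(2).to_string(index=False))
print("\nimportances sum to 100 % over all split features; the ranking "
      "says which baseline measurements best separate the response "
      "clusters in this cohort.")
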