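"""Micro ORI/BON/BLF comparison: one seed, reduced dataset (~2 min).

ORI = naive batches + MSE, BON = fixed-ratio batches + MSE, BLF =
fixed-ratio batches + balanced custom loss.  All three share the dataset
and initial weights; they differ only through batch composition and loss.
The full five-seed comparison is what `scripts/acceptance.py` runs.
"""

from dermbalance.experiments import ExperimentConfig, run_scenario_comparison, summarize_comparison

config = ExperimentConfig(n_pos=94, n_neg=844, epochs=6)  # half-size, fewer epochs
results = run_scenario_comparison(config, seeds=(0,), log_fn=print)
print("\nper-scenario test metrics at threshold 0.5:")
print(summarize_comparison(results).round(3).to_string())
print("\nexpected picture: BLF narrows the |SEN-SPE| gap and lifts SEN "
      "relative to the MSE-trained baselines.")
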