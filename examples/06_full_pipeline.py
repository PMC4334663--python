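"""The whole chain in one call.

Simulates ten hemispheres with a strong planted association, refits every
subject's two dipoles from its simulated evoked fields, extracts ROI
means from synthetic volumes, runs the summed-correlation permutation
test on the *fitted* moments, and performs the Bayesian model and family
comparisons.  Writes a results bundle and prints its report.
"""

from pathlib import Path

from megmyelin import RunConfig, run_all

cfg = RunConfig(
    seed=1,
    out_dir="scratch/example_run",
    association_rho=0.9,
    n_channels=275,
    n_trials=12,
    n_permutations=5000,
    n_restarts=2,
)
bundle = run_all(cfg)
print(Path(cfg.out_dir, "report.txt").read_text())
print(f"full bundle (CSV/JSON) in {cfg.out_dir}/")
print("With a planted rank association of 0.9 across all cells, the")
print("permutation p should be well below 0.05 even though the moments")
print("are re-estimated from noisy sensor data rather than taken as known.")
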