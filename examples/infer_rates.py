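"""Full inference walkthrough on a synthetic strongly repressed strain.

Generates a 5000-cell population at known kinetics (k_a = 9.79,
k_d = 0.10 min^-1), then runs the measurement-side procedure: length
gating, moments, Fano correction, moment inversion, and bootstrap
uncertainty, with r and gamma treated as independently measured.
"""

from telekin import RateParams, RunConfig, generate_population, run_infer

truth = RateParams(r=24.6, gamma=0.79, k_a=9.79, k_d=0.10)
table = generate_population(truth, n_cells=5000, seed=1, operator_label="demo")

config = RunConfig(gamma=0.79, r=24.6, n_bootstrap=1000, seed=1)
report = run_infer(config, table=table)

log, est = report["log"], report["estimate"]
print(f"cells gated      {log['n_cells_gated']} of {log['n_cells_total']}")
print(f"mean mRNA        {log['mu']:.4f}")
print(f"Fano factor      {log['fano']:.4f} -> corrected {log['fano_corrected']:.4f}")
print(f"k_a = {est['k_a']:.3f} min^-1  (truth 9.79), "
      f"80% CI [{est['ci']['k_a'][0]:.3f}, {est['ci']['k_a'][1]:.3f}]")
print(f"k_d = {est['k_d']:.4f} min^-1 (truth 0.10), "
      f"80% CI [{est['ci']['k_d'][0]:.4f}, {est['ci']['k_d'][1]:.4f}]")
# The interval half-widths reflect the sampling noise of the Fano factor
# at this depth; the point estimates should sit within ~15% of truth.
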