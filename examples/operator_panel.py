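"""Simulated operator panel: anticorrelation of inferred rates.

Generates operators along a line where the per-repressor association
rate ka0 falls as the dissociation rate kd rises (strong operators bind
fast and hold long), at several repressor copy numbers with
k_a = n_repressor * ka0.  Each 1000-cell dataset is analyzed twice (raw
counts and counts with per-mRNA intensity noise) and the rank
correlation of inferred log k_a vs log k_d is computed within each copy
number.
"""

from telekin import PanelSpec, run_panel

spec = PanelSpec(n_operators=20, repressor_copies=(1, 10, 100),
                 n_cells=1000, seed=5)
summary = run_panel(spec)

print(f"datasets analyzed        {len(summary.records)}")
print(f"feasible (raw)           {summary.n_feasible}")
print(f"Spearman by copy number  "
      + ", ".join(f"n={n}: {v:+.2f}" for n, v in summary.spearman_by_copy.items()))
print(f"median Spearman (raw)    {summary.spearman:+.3f}")
print(f"median Spearman (noisy)  {summary.spearman_noisy:+.3f}")
# Values near -1 mean the generating anticorrelation between association
# and dissociation rates survives the full inference chain, with and
# without measurement noise.
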