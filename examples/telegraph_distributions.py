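"""Stationary mRNA distributions for a slow and a fast operator.

Two operators with the same binding occupancy (k_a/k_d ratio) share the
same mean expression, but the slowly switching one produces rare large
bursts and hence a broader, longer-tailed copy-number distribution.
"""

from telekin import (
    RateParams,
    analytic_pmf,
    fano_factor,
    mean_expression,
    steady_state_pmf_matrix,
)

slow = RateParams(r=25.0, gamma=0.8, k_a=3.0, k_d=0.18)
fast = RateParams(r=25.0, gamma=0.8, k_a=30.0, k_d=1.8)

for name, p in (("slow", slow), ("fast", fast)):
    pmf = analytic_pmf(p)
    mat = steady_state_pmf_matrix(p, m_max=pmf.m_max)
    dev = max(abs(a - b) for a, b in zip(pmf.probs, mat.probs))
    print(f"{name} operator: k_a={p.k_a} k_d={p.k_d} min^-1")
    print(f"  mean mRNA      {mean_expression(p):8.4f} (pmf: {pmf.mean():.4f})")
    print(f"  Fano factor    {fano_factor(p):8.4f} (pmf: {pmf.fano():.4f})")
    print(f"  P(m=0)         {pmf.probs[0]:8.4f}")
    print(f"  analytic vs matrix oracle, max |diff|: {dev:.2e}")

# Both operators have the same mean; only the Fano factor separates their
# kinetics — that is the entire basis of the rate inference.
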