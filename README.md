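# telekin

Inference of transcription-factor binding kinetics from single-cell mRNA
copy-number distributions, under the two-state ("random telegraph") model
of stochastic gene expression.

## The problem

A repressor bound to its operator silences a promoter; when it falls off,
transcription resumes. The *mean* expression of such a gene only reveals
the ratio of the association rate k_a to the dissociation rate k_d — two
operators with tenfold different kinetics but the same occupancy are
indistinguishable on average. The cell-to-cell *variability* breaks the
tie: slow switching produces rare, large bursts of transcripts and a
long-tailed copy-number distribution, fast switching a nearly Poissonian
one. `telekin` turns that observation into numbers: given a per-cell mRNA
count table (e.g. from smFISH), it recovers the absolute association and
dissociation rates of the repressor for its binding site.

## The model

The promoter is "on" (repressor unbound, transcription at rate r) or
"off" (bound, silent), switching on→off at rate k_a and off→on at k_d;
transcripts degrade at rate γ. All rates in min⁻¹; k_a is a
pseudo-first-order empirical rate at fixed repressor concentration. The
stationary moments are

    μ = (r/γ) · k_d/(k_a + k_d)
    F = σ²/μ = 1 + [k_a/(k_a + k_d)] · r/(γ + k_a + k_d)

With γ measured from a post-rifampicin decay fit (RNA(t) = e^(−γt)) and r
from the unrepressed mean (μ_Δ = r/γ), the measured (μ, F) pair is
inverted exactly for (k_a, k_d); a corrected Fano factor F_c = F − μ/10
removes RNA-polymerase copy-number variability first. Cells are gated to
lengths 1.73–2.16 μm so one reporter copy is present, and uncertainty
comes from a 1000-replicate cell bootstrap (10th/90th percentiles).

The full stationary distribution (a confluent-hypergeometric law in the
reduced rates r/γ, k_a/γ, k_d/γ) is also provided, with an independent
master-equation matrix oracle, exact Gillespie simulators (including a
variant where each transcription event occludes the operator for
t_occlude seconds), synthetic-data generators with known ground truth,
and an smFISH spot-quantification stage (3-D maxima detection, disc-sum
quantification with merging, mode-based single-mRNA calibration).

## Worked example

`examples/infer_rates.py` generates a 5000-cell population at known
kinetics (k_a = 9.79, k_d = 0.10 min⁻¹, r = 24.6, γ = 0.79 min⁻¹) and runs
the full measurement-side procedure:

```
cells gated      2415 of 5000
mean mRNA        0.2965
Fano factor      3.2328 -> corrected 3.2031
k_a = 10.172 min^-1  (truth 9.79), 80% CI [8.992, 11.814]
k_d = 0.0978 min^-1 (truth 0.10), 80% CI [0.0876, 0.1111]
```

The gate keeps about half the cells; the mean says the operator is bound
~99% of the time, and the Fano factor well above 1 carries the kinetic
information. Point estimates land within the bootstrap intervals around
the generating truth. The other scripts in `examples/` demonstrate the
analytic/matrix distributions, the occlusion simulation loop, the
simulated operator panel (anticorrelated rates), degradation-rate
fitting, and image-based spot counting; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the library:

```sh
telekin infer --counts counts.csv --gamma 0.79 --r 24.6 --boot 1000 --seed 1
telekin fit-gamma --series decay.csv
telekin panel --out panel_out
```

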