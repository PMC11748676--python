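# Methods

## Model and stationary law

The two-state telegraph model has states (promoter ∈ {on, off}, m mRNA)
with transitions on→off at k_a (repressor binding), off→on at k_d
(unbinding), m→m+1 at r (on only), m→m−1 at mγ. Everything stationary
depends on the rates only through the reductions r̃ = r/γ, k̃_a = k_a/γ,
k̃_d = k_d/γ; absolute units re-enter through the externally measured γ.

The stationary mean and Fano factor are

    μ = r̃ · k̃_d/(k̃_a + k̃_d),     F = 1 + [k̃_a/(k̃_a + k̃_d)] · r̃/(1 + k̃_a + k̃_d)

(the second factor of μ is the unbound fraction). The full stationary pmf
is the classic confluent-hypergeometric law for a two-state birth–death
process,

    P(m) = e^{−r̃} (r̃^m/m!) · (k̃_d)_m/(k̃_a+k̃_d)_m · ₁F₁(k̃_a; k̃_a+k̃_d+m; r̃),

evaluated term-wise in log space. The Kummer-transformed form above has
an all-positive ₁F₁ series, which is numerically stable; entries that
still fail float evaluation fall back to mpmath. This expression is used
in preference to a Gaussian-hypergeometric (₂F₁ at −1) representation
built on the roots α, β of x² − (r̃+k̃_a+k̃_d)x + r̃k̃_d: that form, as
commonly transcribed, fails both the Poisson limit at k̃_a = 0 and the
matrix oracle (deviations ~10⁻²), whereas the confluent form agrees with
the oracle to ~10⁻¹⁴. The α, β roots are still exposed (`burst_roots`)
and their sum/product identities tested.

An independent check is always available: the generator over states
(promoter, m ≤ m_max) is assembled as a dense matrix with reflecting
truncation and its one-dimensional null space computed by SVD
(`steady_state_pmf_matrix`). The analytic and matrix routes are held to
elementwise agreement of 1e−8 across the tested grid (r̃ ∈ [0.5, 40],
k̃_a ∈ [0, 50], k̃_d ∈ [0.01, 50]).

Truncation starts at ceil(r̃) + 10√r̃ + 10 (the unrepressed Poisson
envelope plus margin) and grows geometrically until the excluded tail is
below 1e−8 — exactly 1 − Σ P(m) for the analytic route (entries are
individually exact), a 10·P(m_max) geometric heuristic for the matrix
route, whose adequacy is tested by doubling m_max. Boundary cases
short-circuit: k_a = 0 → Poisson(r̃); k_d = 0 with k_a > 0 → the absorbing
point mass at m = 0; k_a = k_d = 0 → an occupancy error; r = 0 is admitted
(pure decay) and gives the point mass at 0.

## Rate inference

Given measured (μ, F) and known (r, γ), write p_on = μγ/r and
s = k_a + k_d. The Fano equation gives s = r(1−p_on)/(F_c−1) − γ, then
k_d = p_on·s and k_a = (1−p_on)·s. This exact inversion is the primary
path; a 2-D root-finder on the same system acts as a cross-check (must
agree to 1e−8 relative) guarding against algebra errors. Infeasible
moment combinations return structured failures instead of clamped
numbers: `no_repression` (μ ≥ r/γ), `fano_at_poisson_limit` (F_c ≤ 1; the
ratio k_a/k_d = r/(μγ) − 1 is still reported, since the mean alone fixes
it), `negative_switching_scale` (implied s ≤ 0).

The corrected Fano factor F_c = F − μ/10 removes the contribution of
RNA-polymerase copy-number variability seen in live cells. The divisor is
configurable (default 10), and the uncorrected inference is always logged
alongside. Synthetic populations generated by this package contain no
polymerase noise, so the panel driver (`run_panel`) defaults to no
correction; applying it there measurably biases high-mean operators
(k_a + k_d inflated ~2× when F−1 ≲ μ/10 scale) and can flip weak-operator
correlations. The single-dataset driver (`run_infer`) keeps the
correction by default, since its inputs are nominally experimental. At
the strongly repressed reference point the correction costs only ~1–2% of
F−1, well inside the quoted recovery tolerances.

Auxiliary rates: γ comes from unweighted log-linear least squares of
relative decay level on time with zero intercept (each replicate's t = 0
sample defines level 1; untreated controls are excluded); replicates are
pooled for the point estimate and also fitted individually. r = μ_Δ·γ
from the repressor-deletion mean after the same length gating.

Uncertainty: cells are resampled with replacement n_boot times (default
1000); interval bounds are the 10th/90th nearest-rank percentiles of the
feasible replicates and the bootstrap standard deviation is reported as a
secondary summary (both conventions appear in practice). Replicate
streams derive from the seed by fixed increments (seed + 1000003·i,
mod 2³¹), making runs bit-reproducible; more than 50% infeasible
replicates flags the estimate unstable.

The length gate (default 1.73–2.16 μm, inclusive on both ends) selects
cells with a single chromosomal reporter copy, suppressing gene-dosage
variance; bounds are configurable.

## Stochastic simulation

`simulate_trajectory` is an exact SSA over the four reactions;
`sample_population` runs one trajectory per cell from (on, m = 0) for a
burn-in of 10/min(γ, k_a+k_d) capped at 200 min (several relaxation times
of both the mRNA and the promoter), on per-cell substreams. Occlusion
(binding hazard set to zero for t_occlude seconds after each
transcription) is handled exactly by treating the window end as a rate
wall: if the sampled waiting time crosses the wall, time advances to the
wall and the clock restarts with the restored hazard — valid by
memorylessness of the exponential, with no approximation. A unit test
verifies no binding event ever falls inside a window, and a
simulate-then-infer loop confirms that k_a,sim = k_a,exp/(1 − r·t_occ/60)
yields re-inferred rates close to k_a,exp.

## Synthetic data

The generators emulate the study conditions with known truth:

- **Populations**: i.i.d. draws from the analytic pmf (fast path) or SSA
  endpoints (slow path, distributionally cross-checked by KS test).
- **Measurement noise**: each transcript contributes
  Normal(mean 1, sd 0.4) intensity; per-cell sums are rounded to the
  nearest integer and clipped at 0 (clipping is the package's choice for
  the rare negative sums at small m).
- **Operator panel**: n operators with (ka⁰, k_d) linearly spaced along an
  anticorrelated line — defaults k_d ∈ [0.05, 2] min⁻¹ against
  ka⁰ ∈ [0.2, 0.005] min⁻¹ per repressor, artifact defaults chosen to
  span strong-to-weak binding; k_a = n_repressor·ka⁰ with copy numbers
  {1, 2, 5, 10, 50, 100}; r = 22 min⁻¹, γ = 0.80 min⁻¹, 1000 cells per
  dataset.
- **Decay series**: exp(−γt) on the 2-min grid t = 0…8 with lognormal
  noise, renormalized to the t = 0 draw; optional flat controls.
- **Cell lengths**: lognormal, median 1.93 μm, log-sd 0.17, truncated to
  the observed 1.4–3.25 μm span, so the single-copy gate passes roughly
  half the cells.
- **Images**: each mRNA is a 3-D Gaussian focus (σ_xy = 1.2 px,
  σ_z = 1 plane) of brightness Normal(1, 0.4)× a unit intensity, placed
  inside its cell's mask (non-overlapping by default; an overlap mode
  exercises merging), on a Poisson background. Brightness is defined as
  the focal-plane integrated intensity — the same single-plane quantity
  the quantification pipeline measures.

What the generators deliberately omit: extrinsic noise (RNAP and
repressor copy fluctuations, growth-rate variation), cell growth and
division, gene-dosage beyond the length gate's purpose, partial or
decaying transcripts (which distort the 0/1-mRNA bins in real data), and
realistic optics (no Airy rings, aberrations or chromatic shifts).
Passing tests therefore demonstrate the correctness of the estimator
chain under the stated model, not robustness to every real-data artifact.

## Spot quantification

Stacks are smoothed with σ_xy = 1 px, σ_z = 0.7 planes; strict 3-D local
maxima (26-connectivity, plateau ties broken to the first voxel, maxima
within 2 px of the xy border discarded) above a threshold become calls.
The threshold is the smallest value at which at most k_max = 3 maxima
survive in a matched negative control (k_max = 0 gives a threshold above
the control's noise ceiling). Each call is quantified as the
control-subtracted sum over pixels whose centres lie within 5 px of the
maximum, in the single plane of the maximum; same-plane calls with
overlapping discs are merged (union-region sum, brightest peak kept), a
union-find step that is idempotent and order-independent. Single-mRNA
intensity is the mode of the spot-intensity histogram in a strongly
repressed sample (Freedman–Diaconis bins by default, ties to the lower
bin); per-cell counts are summed spot intensity divided by that unit,
kept real-valued (a rounding switch exists). High-expression
(repressor-deletion) samples instead use the brightest-plane whole-mask
sum, background-corrected, divided by the same unit.

## Problem sizes and numerical conventions

Default study sizes: 5000-cell populations (20 seeds, medians reported)
for rate recovery; 200 repetitions of 3-replicate decay fits; 10000-cell
SSA populations for moment checks; 25–50-operator panels at 1000 cells
per dataset. These match the regimes the estimators are designed for
while keeping full runs in seconds to minutes on one CPU. Results
serialize with 6 significant digits, which is the determinism contract
across platforms. Panel correlations are computed within each repressor
copy number (pooling copy numbers would mix the k_a = n·ka⁰ scaling into
the operator effect) and summarized by the median; Spearman is primary,
Pearson-on-logs secondary.

## Known limitations

- Moment-based inversion only: the analytic pmf is used for overlays and
  goodness checks, not for maximum-likelihood fitting.
- The estimator variance is dominated by the sample Fano factor; for
  weakly repressed operators (F − 1 small) estimates degrade and
  measurement noise — which adds a near-constant Fano increment — hurts
  them most.
- Steady state only; no time-dependent solutions, no protein-level
  distributions, no multi-state promoters.
- Cell segmentation is out of scope; masks are inputs.
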