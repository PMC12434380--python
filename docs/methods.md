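# Methods

## The prediction model

For participant *i*, the connectome is the symmetric matrix of Fisher
r-to-z transformed Pearson correlations between regional time series,
zᵢⱼ = atanh(clip(r, ±(1−10⁻⁷))); clipping keeps perfectly (anti)correlated
series finite, which downstream strength sums require.  The diagonal is
stored as 0 and never used.  Edges are the strict upper triangle in
row-major order with i < j (0-based internally; files write 1-based ids
and say so) — E = N(N−1)/2 edges, 61,776 at the default N = 352
(333 cortical + 19 subcortical regions).

Screening correlates each edge with the follow-up severity score by
partial Spearman correlation: all variables are rank-transformed
(average ranks on ties), ranked edge and ranked outcome are residualized
on the ranked covariates plus an intercept by least squares, and ρ is the
Pearson correlation of the residuals.  The covariate set is fixed as
(baseline score, sex coded F=1, age, mean framewise displacement).
p-values use the t approximation t = ρ√((n−2−k)/(1−ρ²)) on n−2−k degrees
of freedom — accurate at the hundreds-to-thousands of participants per
split this design targets; exact permutation p-values for tiny samples
are out of scope.  Retention is strict: p < α, default α = 10⁻³.

Network strength is Σ|z| over retained edges — a single combined score,
not the positive/negative two-network variant — and an OLS line maps
strength to outcome.  Prediction performance is the partial Spearman ρ
between observed and predicted follow-up scores given the four
covariates, on held-out sites.

Screening is covariate-adjusted by default (the consensus-network
definition); `adjust=False` reproduces the plain-Spearman screen.  Both
modes are recorded in every mask's provenance.

## Cross-validation and the permutation null

Sites are partitioned at random, ⌈S/2⌉ to training (the odd-S convention
is fixed and logged); participants follow their site, so train/test sets
are disjoint by construction, and family leakage is impossible whenever
families do not span sites (the generator guarantees this; a warning
fires if user data violate it).  Iterations (default 100) redraw the
partition.  Iterations whose screen retains zero edges have no defined
prediction; they are excluded from the mean with a logged count rather
than scored as ρ = 0, which would bias the mean toward zero.  The count
is part of the result so instability is visible.

The permutation test shuffles the linkage between connectome rows and
complete phenotype records — outcome and covariates move together, so the
covariate–outcome structure of the evaluation is preserved.  Permutations
are *paired* with the observed run: each permutation reuses the observed
site splits and re-randomizes only the linkage.  Conditional on the
splits, observed and permuted statistics are then exchangeable under the
null, which is what makes p_perm — the strict proportion of permuted mean
ρ exceeding the observed mean ρ — calibrated.  For the same reason
`perm_iterations` defaults to `n_iterations`: averaging the null runs
over fewer iterations than the observed run would widen the null
distribution and make the test conservative.  A (1+#≥)/(1+P) p-value
variant exists but is off by default; ties count as "not larger".
All randomness flows from one master seed through a documented
`SeedSequence` split (splits first, permutations second).

Inside the permutation loop, screening uses ordinal ranks (ties broken
by stable sort order) computed from a per-edge sort order built once per
cohort; for continuous connectivity values ties occur with probability
zero and ordinal equals average ranking, which a test asserts against the
public screen.  This is what makes 200 permutations × 20 iterations ×
100 replicate cohorts tractable on one CPU.

## The synthetic cohort generator

The generator emulates the structure of restricted multi-site
developmental cohorts.  Latent vulnerability v ~ N(0,1) is shared within
families with intra-family correlation 0.5 (no published value exists;
any positive value exercises the leakage risk that site-splitting
guards against).  Families are sibling pairs covering `family_rate` of
participants (default 0.2), always co-sited.

Scores: (u_base, u_y1) are standard bivariate Gaussian latents built from
v plus shared and fresh noise, with loadings `v_loading_base` = 0.15 and
`v_loading_y1` = 0.4.  The weak baseline loading is deliberate: it makes
the planted edges carry *prospective* signal that survives adjustment for
the baseline score, which is exactly the phenomenon the pipeline exists
to detect (a large shared loading would let the baseline covariate absorb
nearly all of it).  Positive skew is induced by the monotone
sinh-arcsinh shift f(u) = sinh(asinh(u) + ε), which preserves the rank
structure Spearman statistics use; the latent correlation is calibrated
by Gauss–Hermite quadrature so that the *post-transform* Pearson
correlation hits the target (0.68 / 0.63 in the presets).  Each cohort is
then affinely standardized to the target mean/SD exactly (correlations
are unaffected).  The clinical/control mixture of the single-site preset
is expressed through group-specific score moments taken from the
published subgroup descriptives; the common within-group correlation is
solved from the pooled-correlation identity.

Edges are generated directly in z-space (time series at E = 61,776 would
be pointless overhead): per-edge baseline level N(0.25, 0.2²) — planted
edges pinned at 0.25 — plus a per-(site, edge) offset N(0, 0.05²), plus
participant noise N(0, 0.2²), plus γ·vᵢ on the planted edges.  The
planted set is drawn from its own `planted_seed` so cohorts sharing a
configuration share their planted edges (the discovery → extension
transfer scenario).  `gamma_for_marginal_r` inverts
r = γ·b_v/√(γ²+σ²_site+σ²_edge) to hit a target marginal edge–outcome
correlation.  A small time-series mode draws multivariate-normal series
whose correlation targets tanh(z) per participant
(eigenvalue-clipped to positive definite), for end-to-end tests at small
N.  Head motion is log-normal (mean 0.12 mm, SD 0.05) with an optional
latent correlation to the outcome (default 0, matching the reported
near-zero motion–outcome association) for stress-testing the covariate
machinery.

What the generator does **not** emulate: autocorrelated hemodynamics,
scanner-specific artifacts, global-signal structure shared across edges,
non-linear brain–behavior coupling, missingness, and attrition.  Passing
tests therefore certify the statistical machinery — screening power and
error control, calibration of the permutation test, leakage-free
splitting — not performance on real connectomes.

## Benchmark scales and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
package's own benchmark sizes: null calibration uses n = 500, 46 regions
(E = 1,035 — the smallest edge space above 10³; no integer N gives
exactly 1,000), 6 sites, 20 CV iterations, 200 permutations, 100
replicate cohorts; the planted benchmark uses n = 2,000 with K = 20
planted edges at marginal r ≈ 0.15.  Preset-calibration checks draw
cohorts at a reduced region count because scores are independent of the
edge space.  Degenerate inputs (constant outcome, zero-variance regions,
rank-deficient covariates, empty masks) raise informative errors rather
than propagating NaNs; an empty consensus mask is a warning, since a
strict threshold legitimately may select nothing.

## Known limitations

* The α-robustness of the prediction (mean ρ varying little across
  selection thresholds 0.05–0.001) does **not** hold on the concentrated
  planted benchmark: at α = 0.05 roughly E·α ≈ 52 false edges enter the
  |z| strength sum and dilute the 20 strong true edges, lowering mean ρ
  at the loose endpoint by ~0.06–0.09.  That robustness is a property of
  weak, diffuse effect structures (where selection dilution is small
  relative to signal), not of the pipeline itself; with a concentrated
  strong planted set the dilution is structural.
* MAE/RMSE in external validation depend on a strength→score calibration
  line.  Which cohort should supply it is genuinely ambiguous; the
  default refits on the extension cohort and records that choice in the
  result rather than guessing.
* The exact published normalization arithmetic for network-pair counts
  is not fully specified upstream; `pair_counts` emits both the
  ratio-of-proportions normalization (used for the >1 overrepresentation
  flag) and the raw observed/possible ratio, clearly labelled.
* The p-value t approximation is anti-conservative below n ≈ 20;
  screening refuses to run there.
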