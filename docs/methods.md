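# Methods

## Data model and conventions

A measurement is a row of a flat CSV: δ¹⁵N_bulk (per mil vs. air-N₂),
δ¹⁸O (per mil vs. VSMOW), optionally the isotopomer deltas δ¹⁵Nα / δ¹⁵Nβ
and the site preference SP = δ¹⁵Nα − δ¹⁵Nβ, one of eight category labels
(Antarctic, freshwater, groundwater, marine, soil, stratosphere,
troposphere, urban wastewater), and the metadata the mixing filters need
(N₂O concentration in ppb v/v for soil-profile gas, percent saturation
and depth for dissolved samples, an emitted-N₂O flag, a flux weight).
Deltas are carried as per-mil floats throughout; missing optional fields
are explicit `None`, never zero. On parse, SP and bulk δ¹⁵N are derived
from the isotopomers when absent, and rows violating the isotopomer
identities by more than 0.05 ‰ are rejected with a recorded reason —
every rejection is enumerated in the parse report, never silent.

δ¹⁸O values reported against atmospheric O₂ are converted to the VSMOW
frame with the exact scale shift `δ_new = δ + δ_ref + δ·δ_ref/1000`. The
offset of atmospheric O₂ vs. VSMOW defaults to +23.88 ‰ (the modern
consensus value) and is an explicit argument, since compilations differ
at the second decimal.

## Mixing filters

Low-concentration soil and surface-water data largely record tropospheric
N₂O rather than the source, so only measurements carrying a demonstrable
source signal are retained, from the three flux-relevant categories:

- any direct report of emitted N₂O (`is_emitted`), regardless of flux
  strength — flux-chamber provenance cannot be inferred from deltas, so
  it is carried as an explicit flag;
- soil-profile gas with concentration **strictly** above 650 ppb v/v
  (≈ 200 % of ambient; the parenthetical is an equivalent restatement,
  not a second rule);
- dissolved N₂O strictly above 200 % saturation, in freshwater or in the
  top 100 m of the ocean (a record without a depth is treated as a
  surface sample).

A record eligible for a criterion but missing the metadata it needs is
excluded and counted under "insufficient metadata" — never retained by
default. All thresholds are strict inequalities, and the filter is
idempotent. The continental source is the pooled soil + freshwater
subset, relabelled.

## Standard ellipses

The standard ellipse of a bivariate sample is the 1σ contour of the
sample covariance matrix Σ (n−1 denominator): centred on the mean, with
semi-axes a ≥ b equal to the square roots of the eigenvalues of Σ
(computed in closed form from σₓ, σ_y, r) and major-axis inclination
θ = ½·atan2(2·cov, σₓ²−σ_y²) mapped into [0, π). For bivariate-normal
data it contains 1 − e^{−1/2} ≈ 39.35 % of the points. The sample-size
corrected area is SEAc = π·a·b·(n−1)/(n−2).

Numerical choices: the slope of the major axis is reported as tan θ but
computed as (λ₁ − σₓ²)/cov when cov ≠ 0, which is stable when θ → π/2
(for the filtered marine source, θ = 1.54 rad, slope ≈ 30.9, where the
tangent of the rounded angle would be wildly off). For a circular cloud
(σₓ = σ_y, r = 0) the orientation is undefined and θ is reported as 0.
Exactly collinear input yields a degenerate summary (b = 0, area 0)
rather than an error; n < 3 is an error. Tangency points of the
axis-parallel tangent lines are (x̄ ± σₓ, ȳ ± r·σ_y) and
(x̄ ± r·σₓ, ȳ ± σ_y); each lies on the ellipse boundary and on the
corresponding regression line.

OLS and the Mann-Whitney test delegate to scipy (`linregress`,
`mannwhitneyu`); the rank-sum test uses exact enumeration when
n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie correction.

## Two-box tropospheric mass balance

The budget `Burden·∂δ_trop/∂t = ΣSources·(δ_src − δ_trop) − ε·L` is used
in its steady-state rearrangements only (no forward time integration):

- source signature: δ_src = (Burden·trend + ε·L + ΣSources·δ_trop)/ΣSources;
- ocean flux: F_ocean = (Burden·trend + ε·L + ΣSources·(δ_trop − δ_cont))
  / (δ_ocean − δ_cont), with F_cont = ΣSources − F_ocean by construction,
  so the partition closes exactly;
- the net isotope flux from the stratosphere is −ε·L;
- the sensitivity scenario moves dL Tg N/yr from the stratospheric loss
  to the total source (L − dL, ΣSources + dL).

Default parameters (per isotope): burden 1553 ± 21.742 Tg N; tropospheric
trends −0.035 ± 0.002 (δ¹⁵N) and −0.022 ± 0.004 ‰/yr (δ¹⁸O); ΣSources
17.9 Tg N/yr and stratospheric loss 14.3 Tg N/yr, each with 25 % relative
1σ; apparent enrichment factors ε = −14.9 ± 0.5 ‰ (¹⁵N) and −13.5 ± 0.5 ‰
(¹⁸O); tropospheric deltas 6.55 ± 0.47 and 44.40 ± 0.34 ‰ (the compiled
troposphere-category SDs are used as the δ_trop uncertainty); continental
endmember −13.11 ± 11.51 and 34.32 ± 10.96 ‰; ocean endmember
5.14 ± 1.93 and 44.76 ± 3.62 ‰ (the filtered-source statistics).

Uncertainty is propagated by Monte Carlo rather than first-order Taylor
expansion because F_ocean is a ratio whose denominator (δ_ocean − δ_cont)
has a large relative uncertainty. Deltas, trends and ε are drawn
Gaussian; the physically positive quantities (burden, ΣSources, L) are
drawn from moment-matched lognormals. The lognormal choice matters: a
zero-truncated Gaussian with 25 % relative σ leaves enough mass near
ΣSources → 0 that the 1/ΣSources term makes the sampled σ of δ_src
unstable (7–19 ‰ across seeds at 10⁵ draws); the lognormal, the standard
positive-support model for a rate known to ±25 %, gives a stable
σ ≈ 5 ‰. Within a draw, the single ΣSources value is used everywhere it
appears, since it is physically one quantity. Both the sample SD and a
robust spread (half the central 68.27 % interval) are reported: for the
flux partition, whose ratio distribution is heavy-tailed whenever a draw
brings δ_ocean close to δ_cont, the sample SD is dominated by those
near-singular draws and the percentile spread is the meaningful summary.
Point-estimate comparisons against printed values round half away from
zero at the printed precision.

## Bayesian mixing model

Source proportions p (soil, freshwater, marine) on the simplex are given
a Dirichlet(α) prior (default α = 1) and the weighted-variance mixing
likelihood: tracer j of the mixture is Normal(Σ_k p_k·μ_kj,
√(Σ_k p_k²·σ_kj² + τ_j²)), with per-source tracer means/SDs computed
from the filtered data and τ the mixture measurement SD. This is the
fully-specified mixing likelihood; hierarchical process/residual error
structures and covariates are deliberately out of scope.

Sampling is random-walk Metropolis in additive-log-ratio coordinates
z_k = log(p_k/p_K) (the softmax parameterization); the target includes
the transform's log-Jacobian Σ log p_k, so prior-only runs marginalize
to exactly Dirichlet(α) — verified against the Beta-marginal closed
forms. The proposal scale adapts toward a 30 % acceptance rate every 200
iterations during burn-in only, preserving detailed balance afterwards.
Default chain configuration: 300 000 iterations, 200 000 burn-in,
thinning 50 (two tracers) or 100 (three tracers), 3 chains; per-chain
RNG streams are spawned from one master seed, so runs are reproducible.
Tests use shorter chains (≈ 10⁴–3·10⁴ iterations), which the 2-D
posterior mixes well within.

Convergence is monitored per proportion with the Gelman-Rubin potential
scale reduction factor, √(((n−1)/n·W + B/n)/W), defined as exactly 1
when the between- or within-chain variance is zero, with R̂ > 1.1
raising a warning; and with the Geweke z score comparing the first 10 %
to the last 50 % of a chain, with standard errors from the spectral
density at zero frequency (Bartlett-windowed autocovariance with lag
cutoff 2·n^{1/3}).

Label-permutation equivariance holds statistically, not bitwise: the
random-walk proposal noise is drawn componentwise, so permuting source
labels yields the permuted posterior up to Monte-Carlo error, which is
what the test asserts.

## Synthetic data generator

Each category is generated as a correlated Gaussian cloud in (δ¹⁵N, δ¹⁸O)
— optionally (…, SP) — with the compiled per-category means, SDs and
correlations as defaults. Gaussian clouds are the natural choice here
because the standard ellipse is exactly their 1σ contour; heavy-tailed
alternatives are out of scope. SP summary statistics are not part of the
compiled tables, so the SP defaults are illustrative values that keep
soil and freshwater separated in δ¹⁵N–SP space, with SP–δ¹⁵N correlation
0 by default.

Metadata are drawn from simple models chosen once so that expected
retention under the mixing filters approximates the compiled data's
(~90 % soil, ~71 % freshwater, ~12 % marine): soil concentration
lognormal(ln 2000, 0.8) ppb; freshwater saturation lognormal(ln 350, 1.0) %;
marine saturation lognormal(ln 150, 0.7) % with depth uniform on
0–300 m; 5 % of source-category records flagged as emitted; flux weights
lognormal(0, 1). These models exist to exercise the filters and the
flux weighting; they do not emulate the real compilation's covariance
between metadata and isotope values (in real profiles, concentration and
δ are physically linked through consumption and mixing), nor its uneven
per-study record counts. Passing tests therefore demonstrate that the
machinery is correct under the stated statistical structure, not that
the filters would reproduce a specific real compilation's retention
counts.

Because filtering acts only on metadata, which the generator draws
independently of the deltas, filtered synthetic subsets have the same
isotope distribution as their parent categories — which is what the
pipeline-level recovery tests exploit.

## Problem sizes and determinism

The test suite runs the containment check at 2·10⁵ points, Monte-Carlo
propagation at 10⁵ draws, mixing recovery at 20 replicates × 3 chains ×
30 000 iterations, and the end-to-end pipeline at a 0.25 scale of the
compiled category sizes with 12 000-iteration chains — sizes at which
every stochastic assertion has comfortable margin while the whole suite
completes in about a minute. All stochastic stages take explicit seeds;
the pipeline spawns per-stage seeds from one master seed and logs them,
and rerunning with the same configuration is byte-identical.

## Known limitations

- The box model treats the troposphere as one well-mixed box and only
  its steady-state rearrangements are implemented; firn/ice-core
  reconstructions of the pre-industrial source are out of scope.
- The ¹⁸O budget yields a negative ocean flux under the default
  parameters (the δ¹⁸O separation between troposphere and continental
  source is too small); the sensitivity scenario shows a 4 Tg N/yr shift
  between loss rate and total source is enough to change its sign —
  i.e., the oxygen budget does not currently constrain the partition.
- Saturation is taken as a provided field; no solubility computation
  from temperature/salinity is performed.
- The mixing model has no covariates, random effects or trophic-style
  offsets, and source statistics are plug-in sample moments rather than
  hierarchically estimated.
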