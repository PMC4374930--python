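# n2oiso

Global nitrous-oxide (N₂O) source apportionment from stable-isotope data.

N₂O is a strong greenhouse gas and the dominant driver of stratospheric
ozone loss, and its atmospheric burden keeps rising. Because microbial
N₂O from soils, freshwaters and the ocean carries distinct stable-isotope
signatures (δ¹⁵N vs. air-N₂, δ¹⁸O vs. VSMOW, and the ¹⁵N site preference
SP = δ¹⁵Nα − δ¹⁵Nβ), compilations of *in situ* isotope measurements can
constrain how much each source contributes to the global budget. This
package implements that analysis chain for researchers working with
N₂O isotope compilations:

1. **Data model & I/O** (`isotope_data`) — an S1-style flat CSV schema of
   measurements with category, filter metadata and flux weights;
   reference-frame conversion (δ¹⁸O vs. atmospheric O₂ → vs. VSMOW) and
   isotopomer arithmetic.
2. **Source filters** (`source_filters`) — exclusion of measurements
   dominated by mixing with tropospheric N₂O: keep direct emission
   reports, soil-profile gas > 650 ppb v/v, and dissolved N₂O > 200 %
   saturation in freshwaters and the top 100 m of the ocean; pooling of
   the continental (soil + freshwater) source; flux-weighted averages.
3. **Standard ellipses** (`ellipse_stats`) — the bivariate 1σ ellipse
   (mean centre, covariance-eigenvalue semi-axes a, b, orientation θ,
   sample-size-corrected area SEAc = π·a·b·(n−1)/(n−2)), containment
   fractions, tangency points, OLS and the Mann-Whitney rank-sum test.
4. **Two-box mass balance** (`box_model`) — the tropospheric budget
   `Burden·dδ/dt = ΣSources·(δ_src − δ_trop) − ε·L`, solved for the
   flux-weighted modern source signature and the ocean/continental flux
   partition, with Monte-Carlo uncertainty propagation.
5. **Bayesian mixing model** (`bayes_mixing`) — Dirichlet-prior posterior
   over source proportions p on the simplex under the weighted-variance
   mixing likelihood, sampled by random-walk Metropolis on log-ratio
   coordinates, with Gelman-Rubin and Geweke diagnostics.
6. **Synthetic data** (`synthetic_data`) — seeded generator of correlated
   Gaussian isotope clouds with filter metadata and flux weights, so the
   whole pipeline runs and is testable with no external data.

## Worked example

```python
from n2oiso import BoxModelParams, propagate_uncertainty, ellipse_from_moments

res = propagate_uncertainty(BoxModelParams.nitrogen(), n_draws=100_000, seed=0)
print("delta15N_sources = %.1f +/- %.1f permil" % (res.delta_sources, res.sd["delta_sources"]))
print("F_ocean = %.1f Tg N/yr (+/- %.1f, 68%% spread; %.0f%% of all sources)"
      % (res.f_ocean, res.robust_sd["f_ocean"], 100 * res.ocean_fraction))
print("F_cont  = %.1f Tg N/yr (+/- %.1f; %.0f%%)"
      % (res.f_cont, res.robust_sd["f_cont"], 100 * res.cont_fraction))

e = ellipse_from_moments(5.14, 44.76, 1.93, 3.62, 0.0435, 62)  # filtered marine source
print("marine ellipse: a=%.1f b=%.1f theta=%.2f SEAc=%.0f" % (e.a, e.b, e.theta, e.area_c))
```

prints

```
delta15N_sources = -8.4 +/- 5.2 permil
F_ocean = 4.6 Tg N/yr (+/- 11.7, 68% spread; 26% of all sources)
F_cont  = 13.3 Tg N/yr (+/- 10.1; 74%)
marine ellipse: a=3.6 b=1.9 theta=1.54 SEAc=22
```

The ¹⁵N mass balance attributes ~26 % of the 17.9 Tg N/yr total N₂O
source to the ocean and ~74 % to the continental (soil + freshwater)
source; the marine standard ellipse is the small, nearly axis-aligned
ellipse (r = 0.04) that sets the ocean endmember apart from continental
N₂O in δ¹⁵N–δ¹⁸O space. The wide spread on the flux partition reflects
the large continental-source variability (1σ ≈ 11.5 ‰ in δ¹⁵N).

A shell pipeline is also available:

```bash
n2oiso simulate --out data.csv --seed 1
n2oiso filter data.csv filtered.csv --report retention.json
n2oiso ellipses filtered.csv ellipses.csv
n2oiso boxmodel --isotope 15N --mc-draws 100000 --seed 1
n2oiso run-all --outdir out/ --seed 1
```

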