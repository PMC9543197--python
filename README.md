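# tailsync

Tail-dependent spatial synchrony analysis for site-by-year panel data.

Populations that fluctuate together across space may do so asymmetrically:
synchrony can be stronger when abundances are high (synchronized booms) or
when they are low (synchronized crashes).  `tailsync` implements a complete
pipeline for detecting and explaining this *tail dependence* in spatial
synchrony, built around giant-kelp-style data — annual biomass on 0.5 km
coastline segments with wave, nutrient and climate-index drivers — but
applicable to any site×year panel with site coordinates.

## The statistics

For two positively associated series with normalized ranks
`u_t = rank(x_t)/(n+1)`, `v_t = rank(y_t)/(n+1)`, the **partial Spearman
correlation** over a quantile band `0 ≤ b_l < b_u ≤ 1` is

    rho(b_l, b_u) = Σ_{t∈S} (u_t − ½)(v_t − ½)
                    / sqrt( Σ_t (u_t − ½)² · Σ_t (v_t − ½)² ),
    S = { t : b_l ≤ (u_t + v_t)/2 < b_u },

the portion of the classical Spearman correlation contributed by points in
that part of the copula (a point exactly on an interior bound counts half
to each adjacent band, making the decomposition exactly additive).  The
**tail dependence strength** is `D = rho(½,1) − rho(0,½)`: positive when
association is stronger in the upper tails.

Around this statistic the package provides:

- **Surrogate null tests** (`tailsync.surrogates`): Gaussian-copula
  surrogate panels preserving each site's marginal exactly and the pairwise
  Spearman matrix approximately (via `r = 2 sin(πρ_s/6)` and
  nearest-correlation repair), but with no tail asymmetry.  Two statistics
  are referred to the null: the summed tail dependence over site pairs
  (two-sided, 0.025/0.975 quantiles) and the geography statistic
  `1 − cor(M_u, M_l)` (one-sided, significant above the 0.95 quantile,
  p = 1 − quantile).
- **Nonparametric spatial covariance functions** (`tailsync.npscf`):
  penalized cubic-spline smoothing of band-specific synchrony against
  distance, with site-resampling bootstrap 95% envelopes.
- **Spatial GLS regressions** (`tailsync.spatial_gls`): neighborhood-mean
  tail-dependence fields (default 25 km, robustness sweep 10–200 km)
  related by GLS with exponentially decaying spatial error correlation,
  the range (and optionally a nugget) profiled out by REML.
- **A threshold-response population model** (`tailsync.theory_model`):
  `N_i(t+1) = N_i(t) λ(N_i(t)) exp(f(δ(t)) + ε_i(t))` with a sigmoid
  driver response `f`; driver distributions below the threshold produce
  upper-tail-dependent synchrony, above it the mirror image.
- **A synthetic coastline generator** (`tailsync.synthetic_data`) that
  plants the full mechanism — a spatially autocorrelated wave-calmness
  field crossing the sigmoid threshold along the coast, plus linear-response
  control drivers — so the entire pipeline can be exercised end to end
  with known ground truth.

## Worked example

```python
import numpy as np
import tailsync as ts

bundle = ts.generate(ts.CoastlineSpec(), seed=5)          # synthetic coast
kelp = ts.detrend_linear(bundle.kelp)                     # per-site detrend
sync = ts.pairwise_synchrony(kelp)                        # M_u, M_l, D

iu = np.triu_indices(kelp.n_sites, k=1)
d = ts.great_circle_distance_matrix(bundle.sites).d[iu]
rho = (sync.m_upper + sync.m_lower)[iu]
print(f"synchrony <5 km: {rho[d < 5].mean():.3f}, "
      f"100-300 km: {rho[(d >= 100) & (d < 300)].mean():.3f}")

wave = ts.detrend_linear(bundle.wave_calmness)
prof = ts.driver_tail_profile(kelp, wave)                 # site-level D
below = np.asarray(bundle.truth["below_threshold"])
print(f"mean kelp-calmness tail dependence: "
      f"exposed sites {prof['d'][below].mean():+.3f}, "
      f"sheltered sites {prof['d'][~below].mean():+.3f}")
```

prints

```
synchrony <5 km: 0.590, 100-300 km: 0.117
mean kelp-calmness tail dependence: exposed sites +0.163, sheltered sites -0.166
```

Synchrony decays with distance, and the sign of the kelp–calmness tail
dependence follows each site's side of the response threshold: wave-exposed
sites (mean calmness below the threshold) associate more strongly with the
driver in the upper tails, sheltered sites in the lower tails — the
signature the spatial regressions then tie to tail-dependent synchrony.

A command-line interface mirrors the pipeline stages
(`tailsync synth | preprocess | synchrony | test | npscf | gls | theory`);
every stochastic stage takes `--seed`.

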