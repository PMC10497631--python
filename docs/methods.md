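# Methods

## Model

The soil profile is a vertical cascade of well-mixed annual boxes. For
layer *k* and year *t*:

    S[k,t] = (1 − Z_k) S[k,t−1] + X_k I[k,t] Δt          (stock update)
    D[k,t] = (1 − X_k) I[k,t] + Z_k S[k,t−1]/Δt − A[k,t] (drainage)
    I[1,t] = R_t + L_t ;  I[k,t] = D[k−1,t]  for k > 1

The pair is an exact balance — `I = ΔS/Δt + D + A` holds identically — and
the implementation preserves it to machine precision (asserted ≤ 10⁻⁹
relative in the tests). Within one year, layers are updated from the
surface downward so that the *same-year* drainage of layer k−1 feeds
layer k; any other order breaks conservation.

Assumptions inherited from the study design this emulates:

- annual time step (Δt = 1 yr) smoothing seasonal variation; no sub-annual
  dynamics, no lateral transfer, no gas-phase chlorine;
- no humus compartment (mull humus turns over in under a year);
- stable Cl at steady state in a mature forest, hence
  `Σ_k A_k,t = L_t` (roots return annually what litterfall delivers) and
  the per-layer Cl input cascade `I_1 = R + L`, `I_{k+1} = I_k − A_k`;
- no isotopic fractionation between ³⁵Cl and ³⁶Cl anywhere in the cycle,
  hence equal residence times for the two species and the pre-bomb
  initialization `S₀(³⁶Cl) = I(³⁶Cl) T_R(Cl)`;
- root absorption decays exponentially with depth; layer weights are the
  integrals of `exp(−z/z₀)` over the layer, normalized profile-wide.

Derived timescales (steady-state algebra, applied per accepted draw):
`T_R = S/I`, `Z = XΔt/T_R`, `T′ = S/(XI) = T_R/X`. `T′` is the retention
duration of organically fixed chlorine — the proxy for the median age of
active SOC. Feasibility requires `Z ≤ 1`: draws with `X > T_R/Δt` would
release more than the standing stock each year and are rejected as
infeasible, never accepted.

### ³⁶Cl root absorption

Passive, non-fractionating uptake means roots absorb ³⁶Cl in proportion to
the isotopic ratio of the water they drink. Two modes are implemented:

- `mobile` (default): `A(³⁶Cl) = A(Cl) × [mobile-pool ratio]`, where the
  mobile pool is `(1−X)I + Z S_prev/Δt` for each species. This is the
  solution actually present in the layer. By construction absorption can
  never exceed the mobile pool in this mode.
- `rainfall`: the year's rainfall ratio instead; drainage is clamped at
  zero (and the event logged) if absorption would overdraw the pool.

Which convention the original analysis used is not documented; `mobile` is
the declared default here because it is internally consistent with the
box state. The choice has little effect on stocks (absorption only
partitions the outflow between roots and drainage).

## Forcing

³⁶Cl rainfall input = constant cosmogenic background (set to the modern
flux measured at the site) plus the 1952–1972 bomb-test anomaly. The
anomaly is parametric: gamma-shaped annual weights over the window
(default shape 4, peaking in 1963, configurable), scaled so that the
window-integrated anthropogenic deposition equals
`amplitude × background × 21 yr` with `amplitude = 10³` by default —
i.e. a pulse three orders of magnitude above background on average, peaking
near 2.5 × 10³. A measured/reconstructed deposition series can replace the
parametric pulse via `forcing.csv` (year, species, flux); gaps are an
error unless an explicit fill background is declared. Stable Cl input is
constant (no anthropogenic source). Litterfall input is `λ R_t` with
λ = 0.11 (litterfall carries 11% of the rainfall isotope input at this
kind of site); an experimental recycled mode is deliberately not the
default because the proportional form is the documented forcing.

Simulations run 1940→2020 by default. Because initialization is the exact
pre-bomb steady state, results are insensitive to the start year (1910 vs
1940 agree to < 10⁻⁹ relative in 2010 — asserted by a test), which also
resolves the ambiguity between the two start dates quoted in the source
material for this design.

## Inference

Monte-Carlo rejection (ABC with the measurement uncertainty as kernel),
10,000 replicates by default. Each replicate:

1. perturbs every measured quantity with a zero-truncated normal at its
   recorded 1σ (bulk density 5%; layer thickness, litterfall mass,
   drainage volume 10%; rainfall 3%; concentration uncertainties as given
   in the tables). Carrier amounts are shared between the two species of a
   flux component (one water volume), and the same ρ and d perturbations
   hit both species' stocks — correlations the quadrature bookkeeping
   alone would miss;
2. rebuilds the derived state: stocks, absorption weights, Cl cascade,
   residence times, pre-bomb ³⁶Cl initialization;
3. draws `X_k ~ U(0,1)`, simulates to the stock-sampling year, and accepts
   layer k when `|S_sim − S_obs| ≤ m·σ_obs` with m = 1 (σ_obs is the
   propagated uncertainty of the nominal measured stock; S_obs is the
   replicate's perturbed stock).

Layers are fitted top-down: stage k samples its upstream X's from the
accepted (lowest-branch) draws of earlier stages, so downstream posteriors
inherit upstream uncertainty without the geometric acceptance-rate
collapse of joint rejection. A `joint` mode (accept only when all layers
fit simultaneously) exists and is cross-checked against the sequential
scheme on two-layer profiles; on five layers its acceptance rate is
impractically small, which is why it is not the default.

Accepted X sets are generically multimodal: the stock-vs-X response rises
(more retention) and then falls (faster flushing, since Z = X/T_R), so it
can cross the measured stock twice. The adopted posterior is the lowest
contiguous branch — sort the draws, split at the first gap wider than
`gap_threshold` (default 0.05 in X units), keep the lowest cluster —
consistent with the small retention indicated by measured input/output
flux ratios. Summaries report a normal fit for X (mean ± sd, plus robust
quantiles) and a log-normal fit for T′ (median `exp(μ_log)`, 16–84%
interval `exp(μ_log ± σ_log)`), with branch diagnostics (cluster count,
gap locations) alongside.

### Known limitation: branch geometry

The response peaks at `X* ≈ T_R/Δτ`, where Δτ ≈ 47 yr is the lag between
the pulse centroid (~1963) and the 2010 stock sampling. Layers whose
retention duration is shorter than Δτ sit *past* the peak, so a second,
lower-X solution exists for them; layers with T′ ≫ Δτ sit on the rising
limb and their lowest solution is the physical one. Consequences, measured
on the default virtual site:

- surface layer (T′ ≈ 20 yr): the spurious low cluster and the true
  cluster are ~0.02 apart in X, below the gap threshold, so they merge and
  the posterior median remains a good estimator (the true cluster carries
  ~85% of the mass) while the mean is pulled slightly low;
- mid-profile (T′ ≈ 110 yr): the high-X branch is ~4× wider than the true
  branch and measurement perturbation smears the gap shut, so the merged
  point estimate can sit well above the truth even though the 95% interval
  still covers it;
- deep layers (T′ ≳ 200 yr): branches separate cleanly and the lowest
  branch is the true one.

This is a structural identifiability limit of fitting one stock number per
layer, not a sampling artifact; the branch diagnostics expose it, and the
recovery experiment below quantifies what survives it. Additional
observables (e.g. drainage isotope ratios as a second acceptance
constraint) would break the degeneracy but are beyond the documented
acceptance rule implemented here.

## Synthetic sites

The generator emulates the statistical structure of the study system, and
its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| layers | 0–5, 5–15, 15–30, 30–45, 45–60 cm | Cambisol profile |
| bulk density | 1.05…1.40 g cm⁻³ | increasing with depth |
| SOC | 30 g kg⁻¹ surface-layer mean, e-folding 22.8 cm | exponential decrease; surface/deep ratio 9 |
| X_k | 0.0015 × SOC_k | linear in SOC → surface 4.5%, ninefold decrease |
| T′ truth | 20, 50, 110, 200, 305 yr | retention durations, surface→deep |
| background | 5×10⁸ (³⁶Cl), 1.5×10²² (Cl) at m⁻² yr⁻¹ | ~1 mg L⁻¹ chloride in ~900 mm rain |
| λ | 0.11 | litterfall share of rainfall input |
| carriers | 900 L, 300 g, 400 L m⁻² yr⁻¹ | rain, litter, drainage |
| noise | 5% ρ; 10% d, litter, drainage; 3% rain; 5% concentrations | recorded 1σ, also the realized noise |

The concentration (analytical) uncertainty is a parameter defaulting to 5%
because no measured value is available for it. "Measured" ³⁶Cl stocks are
produced by running the forward model itself from the pre-bomb steady
state to 2010 and perturbing each physically measured factor (density,
concentrations, carrier amounts); depth boundaries stay nominal while
their 10% uncertainty is recorded for propagation. Generator noise draws
are entirely separate from the inference engine's perturbation draws, so
recovery experiments are not circular in the noise model. Truth T′ for
scoring is computed analytically (T_R/X), which is exact.

What the generator does *not* emulate: AMS counting statistics and blank
corrections, seasonal variability, lateral heterogeneity, a saline Cl
pool, humus storage, or a realistic (reconstruction-shaped) pulse time
series. Passing recovery tests therefore demonstrate the pipeline's
internal consistency under the stated noise structure, not performance on
any real site.

## Numerical choices

- Uncertainties are relative 1σ; quadrature for products/quotients.
  Perturbations are zero-truncated normals (stocks and fluxes cannot be
  negative).
- Depth intervals are closed–open `[top, bottom)` cm; layer contiguity and
  ordering are validated on read. CSV tables carry a mandatory units line.
- Soluble-fraction chlorine columns, if present in user tables, are
  ignored by the model: total concentrations are treated as the organic
  stocks.
- Cl input cascade closure `ΣA = L` is enforced to 10⁻⁹ relative.
- Infeasible draws (Z > 1) are counted and excluded; a run that accepts
  nothing raises a diagnostic error reporting the nearest miss in σ units
  rather than returning an empty posterior.
- Drainage clamping (possible only in `rainfall` absorption mode or for
  pathological initial stocks) is logged per (species, layer, year) and
  surfaced in the run summary.
- Posterior summaries need ≥ 30 accepted draws per layer; smaller sets are
  flagged `insufficient` but still reported.

## Problem sizes

Default runs simulate 5 layers × 81 years × 2 species; a 10,000-replicate
rejection fit takes well under a second (the replicate dimension is
vectorized). The recovery experiment in `scripts/acceptance.py` repeats
the full generate-fit-score cycle 50 times (10,000 replicates each) and
completes in roughly 15 s on one CPU; the headline profile numbers are the
median over 5 MC seeds of per-run branch medians, which is robust to the
occasional run in which a deep-layer branch fails to separate.
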