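# cl36soil

Chlorine-36 bomb-pulse tracer modelling of soil organic carbon dynamics.

## The problem

The age of active soil organic carbon (SOC) is a key control on how much
atmospheric CO₂ soils can sequester, but the standard estimates disagree:
¹⁴C-based ages are several times older than those from Earth-system models
and from stable-isotope (δ¹³C) chronosequences. Chlorine-36 offers an
independent clock. ³⁶Cl is a cosmogenic radionuclide (half-life 301 kyr)
whose atmospheric deposition spiked by roughly three orders of magnitude
during the 1952–1972 marine nuclear weapon tests. A fraction of the
chlorine deposited on a forest soil is fixed into organic matter
(organochlorine) and follows SOC dynamics without isotopic fractionation,
so the bomb spike acts as a dated tracer injection: how much of it a soil
layer still holds today tells you how much chlorine input the layer retains
and for how long.

`cl36soil` implements that analysis as a reusable pipeline for layered
soil-profile data (depth intervals, bulk densities, Cl and ³⁶Cl
concentrations with uncertainties, and annual rainfall/litterfall/drainage
fluxes).

## The model

Each soil layer *k* is a box updated at an annual step Δt = 1 yr:

    S[k,t] = (1 − Z_k) · S[k,t−1] + X_k · I[k,t] · Δt
    D[k,t] = (1 − X_k) · I[k,t] + Z_k · S[k,t−1]/Δt − A[k,t]

with surface input `I[1,t] = R_t + L_t` (rainfall + litterfall) and
`I[k,t] = D[k−1,t]` below — each layer drinks the drainage of the one above
it. `X_k` is the fraction of input retained in organic form, `Z_k` the
fraction of the standing stock released per year, `A[k,t]` root absorption
(exponential depth profile, total uptake = litterfall return). Stable Cl is
at steady state in a mature forest, which gives per-layer timescales by
algebra:

    T_R,k  = S_k / I_k            residence time of the total Cl pool
    Z_k    = X_k · Δt / T_R,k     steady-state closure
    T′_R,k = S_k / (X_k · I_k)    retention duration = T_R,k / X_k

`T′` is the mean time an atom spends in the organic pool — the proxy for
the median age of active SOC. The ³⁶Cl side starts from its pre-bomb
steady state `S₀(³⁶Cl) = I(³⁶Cl) · T_R(Cl)` (no fractionation) and is
forced by the bomb-pulse deposition history.

The single free parameter per layer, `X_k`, is inferred by Monte-Carlo
rejection: draw `X_k ~ U(0,1)`, perturb every measured quantity with a
zero-truncated normal at its stated 1σ, simulate from the pre-bomb period
to the stock-sampling year, and accept the draw when the simulated ³⁶Cl
stock matches the measured one within measurement uncertainty. Accepted
sets can be multimodal (a small X that keeps the spike for decades, or a
large X that grabs more of it but flushes it quickly); the adopted solution
is the lowest branch, consistent with the small retention indicated by
measured input/output fluxes.

## Worked example

Generate a truth-known virtual site (a five-layer Cambisol-like beech-forest
profile), fit it, and score the recovery:

```python
import cl36soil as cs

truth = cs.gen_site(1)                                   # known X_k, T'_k
dataset, scenario = cs.gen_observations(truth, noise_seed=777)
sample = cs.run_mc(dataset, config=cs.MCConfig(n_simulations=10_000, seed=11))
summary = cs.summarize_posteriors(sample)
print(summary.table[["layer", "n_accepted", "n_branch", "x_median", "x_sd",
                     "tprime_median", "tprime_lo16", "tprime_hi84"]]
      .round(4).to_string(index=False))
```

```
 layer  n_accepted  n_branch  x_median   x_sd  tprime_median  tprime_lo16  tprime_hi84
     1          89        89    0.0517 0.0224        30.2450      11.7021      78.1706
     2         366       366    0.0486 0.0209        41.0538      25.6391      65.7361
     3         339        65    0.0180 0.0034       138.0615     113.8226     167.4621
     4         235        39    0.0100 0.0016       204.5122     172.8933     241.9137
     5         208        12    0.0051 0.0010       359.5349     311.4101     415.0967
```

Reading this: the surface layer retains ~5% of its annual chlorine input
(the site was generated with 4.5%) and holds it for ~30 yr (16–84%
interval 12–78 yr); retention drops roughly ninefold by 45–60 cm depth
while the retention duration — the proxy SOC age — rises to ~360 yr
(generated: 305 yr). `n_branch` is the size of the adopted (lowest)
solution branch. Scoring against the generating truth:

```python
print(cs.score_recovery(truth, summary)[["layer", "x_true", "x_mean",
      "covered_95", "tprime_true", "tprime_median"]].round(4).to_string(index=False))
```

```
 layer  x_true  x_mean  covered_95  tprime_true  tprime_median
     1  0.0450  0.0441        True         20.0        30.2450
     2  0.0326  0.0476        True         50.0        41.0538
     3  0.0190  0.0178        True        110.0       138.0615
     4  0.0098  0.0101        True        200.0       204.5122
     5  0.0051  0.0050        True        305.0       359.5349
```

Every layer's 95% posterior interval covers the generating value.

The same pipeline runs from the shell:

```
cl36soil synth --seed 3 --out-dir site/
cl36soil fit --layers site/layers.csv --fluxes site/fluxes.csv \
             --seed 5 --n 10000 --out-dir fit/
cl36soil report --posterior fit/posterior.csv --layers site/layers.csv \
                --fluxes site/fluxes.csv --truth site/truth.json --out-dir report/
```

Real site tables use the same CSV formats (`layers.csv`, `fluxes.csv`,
optionally a `forcing.csv` deposition series replacing the parametric
pulse); see `docs/methods.md` for the column and unit conventions.

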