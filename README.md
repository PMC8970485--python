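# dropcult

Simulation and analysis of microbial growth in microfluidic droplets, built
around one question: **how does droplet size shape the dynamics of a
cross-feeding co-culture?**

Water-in-oil microdroplets confine a Poisson-distributed handful of founder
cells in picoliter volumes.  At a fixed encapsulation mean λ, a larger
droplet holds the same expected number of cells in an eight-times-larger
volume, so the initial cell density — and with it the pace at which secreted
metabolites accumulate — falls with the diameter cubed.  For a pair of
amino-acid auxotrophs that can only grow by feeding each other (here the
*E. coli* pair S1 ΔilvD ⇄ S2 ΔlysA, exchanging lysine for branched-chain
amino acids), that dilution can lengthen the lag, depress the apparent
growth rate, or abolish co-growth altogether, depending on how strongly the
partners depend on the exchange.

The package provides:

* `dropcult.droplet_model` — droplet geometry, diffusion-time estimates
  (t = L²/6D), λ ↔ cell-density conversions, and seeded Poisson founder-cell
  sampling with Bernoulli viability thinning;
* `dropcult.crossfeed_ode` — a deterministic Monod-type ODE model of the
  two-auxotroph bi-culture with growth-coupled consumption (β) and
  abundance-coupled secretion (α) of the exchanged amino acids, density
  sweeps across droplet sizes, and classification of the two response
  regimes (Type 1: lag lengthens at unchanged rate; Type 2: rate declines at
  unchanged lag);
* `dropcult.growth_fitting` — fold-change normalization of plate-reader
  curves and least-squares fitting of the lag-modified logistic
  N(t) = K/(1 + (K−1)·e^{−r(t−τ)}) with P0 fixed at 1, returning the growth
  capacity K, maximum specific growth rate r (hr⁻¹), and lag time τ (h),
  plus a brute-force grid-search oracle for verification;
* `dropcult.population_stats` — per-droplet area-normalized endpoint
  distributions, Student's pooled t-test comparisons, λ-variability
  (percent sd reduction), and bi-culture composition ratios;
* `dropcult.synthetic_data` — a fully seeded generator of per-droplet
  trajectories, pooled plate-reader wells, and image-analysis-style endpoint
  tables with founder-driven heterogeneity;
* `dropcult.experiments` / the `dropcult` CLI — drivers chaining the above
  into the three standard in-silico experiments (monoculture size sweep,
  bi-culture interaction levels, α–β regime map).

## Worked example

```python
import numpy as np
import dropcult as dc

print("55 um droplet volume: %.2f pL" % dc.droplet_volume(55))
print("valine diffusion across 150 um: %.2f s" % dc.diffusion_time(150))
print("lambda matching 5 @55um -> 100um: %.1f" % dc.lambda_for_matched_density(5, 55, 100))

t = np.arange(0, 24 + 1/12, 1/6)                      # 10-min reads, 24 h
curve = dc.synthetic_logistic_curve(K=73.0, r=0.79, tau=1.3, time_h=t)
fit = dc.fit_growth_curve(curve)
print("round trip: K=%.1f  r=%.2f /h  tau=%.1f h" % (fit.K, fit.r, fit.tau))

import dropcult.experiments as ex
grid = ex.run_experiment(ex.ExperimentSpec(name="ode_regime_map"))["grid"]
print(grid.pivot(index="alpha", columns="beta", values="label"))
```

prints

```
55 um droplet volume: 87.11 pL
valine diffusion across 150 um: 4.69 s
lambda matching 5 @55um -> 100um: 30.1
round trip: K=73.0  r=0.79 /h  tau=1.3 h
beta         8.000000e-10 2.500000e-09 1.600000e-08
alpha
2.000000e-10        Type1         none         none
6.000000e-10        Type1        Type1         none
2.000000e-09        Type1        Type1        Type2
```

Reading the output: a 55 μm droplet holds ~87 pL, and even across the
largest (150 μm) droplet a cross-fed amino acid diffuses in under five
seconds — diffusion itself is never the hours-scale bottleneck.  Matching
the *density* of λ=5 at 55 μm requires λ≈30 at 100 μm.  The fitter recovers
a noise-free logistic triple exactly.  The regime map shows the two
droplet-size response regimes of the cross-feeding pair: with weak secretion
(small α) dilution stretches the lag at an unchanged rate (Type 1), while a
high requirement (large β) caps growth at the slow exchange-limited rate
α/β, so in larger droplets the apparent rate declines instead (Type 2);
where the interaction is too strenuous, co-growth fails to establish within
the 48-h window (`none`).

The same drivers run from the shell:

```bash
dropcult experiment monoculture_size_sweep --seed 1 --out results/mono
dropcult simulate --config plate.yaml --seed 1 --out raw.csv
dropcult fit --curves curves.csv --out fits.csv
dropcult stats --endpoints endpoints.csv --channel total --out summary.json
```

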