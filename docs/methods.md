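# Methods

`dropcult` simulates and analyzes the growth of microbial mono- and
co-cultures confined in water-in-oil microfluidic droplets, focusing on how
the droplet size — through the initial cell density it implies — shapes the
growth capacity, the maximum specific growth rate, and the lag time of a
cross-feeding pair of amino-acid auxotrophs.

## Droplet geometry and encapsulation statistics

A droplet of diameter *d* (μm) has volume (π/6)·d³, reported in picoliters.
The expected founder-cell count per droplet is λ = ρ·V for an aqueous-phase
cell density ρ; `density_for_lambda` and `lambda_for_matched_density` convert
between the two, so a fixed-density design across sizes rescales λ by
(d₂/d₁)³ (λ = 5 at 55 μm corresponds to λ ≈ 30 at 100 μm and λ ≈ 100 at
150 μm).

Founder counts are sampled i.i.d. Poisson(λ) per strain, reflecting passive
flow-focusing encapsulation with no co-encapsulation correlation between
strains.  A viability probability thins each count binomially (equivalently,
viable counts are Poisson(pλ)); this is the simplest mechanism that
reproduces the observed fraction of droplets that never grow at λ = 5.  The
diffusion-time estimate t = L²/(6D) uses valine's aqueous diffusivity
(800 μm²/s) by default and is reported in seconds: across the 55–150 μm
range it evaluates to ~0.6–4.7 s, always negligible against the hours-scale
of growth.  (The function deliberately carries no unit switching; the
seconds scale is part of the point.)

## The cross-feeding ODE model

Two *E. coli* auxotrophs are modeled: S1 ΔilvD (requires isoleucine, valine,
leucine; supplies lysine) and S2 ΔlysA (requires lysine; supplies the
branched-chain amino acids).  Each strain grows at a multiplicative-Monod
rate

    μ_i = μmax_i · G/(kG_i + G) · Π_a A_a/(k_a + A_a),   a ∈ required AAs

with biomass N_i (cells/mL), shared glucose G (g/L), and amino-acid pools
A_a (mM):

    dN_i/dt = μ_i N_i
    dG/dt   = − Σ_i μ_i N_i / Y_i
    dA_a/dt = Σ_p α_{p,a} N_p − Σ_c β_{c,a} μ_c N_c − δ A_a

Consumption is growth-coupled: β is the amount of amino acid incorporated
per unit of biomass formed.  Secretion is, by default, **abundance-coupled**
(α·N, overflow export per unit biomass per hour).  This choice is
deliberate: if secretion were strictly growth-coupled (α·μ·N, available via
`coupling="growth"`), the exchanged pool would be an algebraic function of
the biomass increase, A = A₀ + (α−β)ΔN; every exchange-limited transient
then becomes autocatalytic and a mutualism with β > α deadlocks outright.
Abundance-coupled export lets an obligate pair bootstrap from near-zero
pools and produces both of the droplet-size response regimes described
below.  A first-order abiotic loss term δ (`aa_loss_per_h`, default 0)
represents degradation or partitioning out of the aqueous phase and is kept
as an option because it is the only term that makes the quasi-steady
exchange level scale with cell density.

Unsupplemented but required amino acids start from a small trace carry-over
pool (5·10⁻³ mM), representing residual metabolite transferred with the
washed inoculum; without some seed concentration a hard multiplicative
auxotrophy can never leave the μ = 0 fixed point.  Supplemented amino acids
enter as finite 3 mM pools subject to consumption — at 3 mM ≫ k_a
(10⁻² mM) they are effectively saturating throughout a cultivation.

Default parameters (configuration, not fitted values): μmax = 0.8 hr⁻¹
(matching the small-droplet monoculture rate scale), k_G = 0.05 g/L,
yield = 8·10⁸ cells·mL⁻¹ per g·L⁻¹ (so 5 g/L glucose supports ~4·10⁹
cells/mL), k_a = 0.01 mM, α ∈ [10⁻¹⁰, 2·10⁻⁹] mM·(cells/mL)⁻¹·hr⁻¹,
β ∈ [8·10⁻¹⁰, 1.6·10⁻⁸] mM·(cells/mL)⁻¹.  Per-amino-acid secretion levels
are scaled inversely to biosynthetic cost (valine 1.5, leucine 1.2,
lysine 0.6, isoleucine 0.25 × the base α): isoleucine is the most expensive
amino acid to overproduce.  This asymmetry is what tips the
isoleucine-supplemented bi-culture toward S1 dominance (composition ratio
> 1) while the more strenuous scenarios are more balanced.  The regime map
uses a uniform scale so its axes stay interpretable.

Integration uses LSODA with rtol 10⁻⁸ and per-component absolute tolerances
scaled to each variable's magnitude; states are clipped at zero after
integration.  The output grid defaults to the 10-minute plate-reader
cadence.  Mass-balance closure (glucose and every amino-acid budget within
1%) and step-refinement stability are asserted in the test suite.

## Growth-curve normalization and fitting

Raw well fluorescence is background-subtracted and divided by the initial
net reading, producing fold-change curves that start at 1.  When no blank is
supplied the background is estimated as the minimum of the first three
readings; readings at or below background are floored just above zero.
Curves are fit by unweighted least squares to the lag-modified logistic

    N(t) = K / (1 + (K−1)·e^{−r(t−τ)}),   P0 = 1 fixed,

with K the growth capacity (fold increase at saturation), r the maximum
specific growth rate (hr⁻¹), τ the lag time (h).  Initialization: K₀ from
the curve maximum, r₀ from the steepest 5-point slope of log values, τ₀ from
the first crossing of 2-fold; bounds K ∈ [1, 10·max], r ∈ [0, 5] hr⁻¹,
τ ∈ [0, t_end]; optimizer `scipy.optimize.least_squares` (TRF).  Flat curves
(max fold < 1.1) are returned as K ≈ 1 with `converged=False` — the rate is
unidentifiable from them.  A brute-force grid search (`fit_oracle_grid`)
serves as an independent cross-check; the optimizer's residual is asserted
never to exceed the best grid point's by more than 10⁻⁸.

Noise-free round trips on the reference monoculture parameter triples
(K = 73.0, r = 0.79 hr⁻¹, τ = 1.3 h at 55 μm over 24 h; K = 598.9,
r = 0.63 hr⁻¹, τ = 3.1 h at 150 μm over 48 h) recover every parameter to
well under 0.5%; with 1% multiplicative read noise the median errors of K
and r stay below 5% over 100 seeded replicates.

## Density sweeps and the two response regimes

Increasing the droplet diameter at fixed λ dilutes the inoculum as 1/d³
while leaving the nutrient pools unchanged, so the growth capacity
K ≈ (yield·G₀)/N₀ rises with droplet volume; at fixed density the
deterministic kinetics are size-invariant.  `sweep_density` runs either
design and fits every fold-change curve; `classify_trend` labels the sweep
using fixed thresholds: **Type 1** if the lag lengthens by more than 25%
while the rate moves by less than 10%; **Type 2** if the rate declines
monotonically by more than 15% while the lag moves by less than 25%;
`mixed`/`none` otherwise.  The 10% rate band comfortably exceeds the ±2%
spread of replicate monoculture rates while sitting well below the 20–40%
declines of strongly interacting sweeps.

The two regimes arise from different bottlenecks:

* **Type 1 (weak secretion).**  The exchanged pool builds at a rate
  proportional to the cell density, so halving the density roughly doubles
  the time to bootstrap the mutualism past k_a.  Once bootstrapped, growth
  runs at the uncapped Monod rate.  The transient is a time shift: the lag
  grows steeply with droplet size while the fitted rate barely moves.
* **Type 2 (high requirement).**  When β is large relative to α the pool is
  pinned at a quasi-steady level and growth proceeds at the exchange-limited
  rate ≈ α/β ≪ μmax.  Within the fixed 48-hour observation window the dense
  (small-droplet) conditions just saturate, but the dilute conditions — with
  20× more fold change to cover at the same capped rate — overflow the
  window.  Fitting the truncated curves yields apparent rates that decline
  gradually with droplet size while the apparent lag stalls.  The finite
  window is essential: with per-capita exchange the quasi-steady rate itself
  is density-independent, so on fully saturated curves all density
  dependence collapses into the lag.  This mirrors the experimental
  situation, where fits are likewise made to fixed-duration plate-reader
  runs.

The default regime map (α ∈ {2, 6, 20}·10⁻¹⁰, β ∈ {0.8, 2.5, 16}·10⁻⁹,
diameters 55/75/100 μm, 48 h) yields Type 1 throughout the low-β region,
Type 2 at the high-β/adequate-α corner, and `none` where the cap is so
severe that no appreciable co-growth establishes within the window — the
in-silico analogue of the co-growth failure seen under the most strenuous
interaction.  The Type 1 and Type 2 regions cannot both extend into the
shared low-α/high-β corner: there the interaction is simply too weak to
sustain growth, and no classification thresholds change that.

## Synthetic data generator

The generator fabricates the two raw-data layouts the analysis consumes and
is the test bench for the statistical machinery.

Per droplet and strain, founder counts are Poisson(λ) thinned by viability.
A droplet with no viable founder of a strain contributes no signal in that
channel (non-viable cells are treated as non-fluorescent); in an obligate
bi-culture (`partner_required`) a missing partner stops growth of all
strains in the droplet.  Growing droplets follow a fold-change kernel that
holds the baseline through the lag and then follows the logistic.  Three
heterogeneity channels act per droplet:

* a growth-rate perturbation with per-founder CV 0.2, averaged over the
  founders (effect ∝ 1/√n);
* a saturated-signal perturbation with per-founder CV 0.3, likewise
  averaged — a stand-in for the persistent cell-to-cell differences
  (plasmid copy number, expression state) that keep endpoint distributions
  broad even at saturation; the real mechanism is not modeled;
* a λ-independent per-droplet gain (CV 0.1) representing image-analysis
  measurement noise; it cancels in fold change but widens endpoint
  distributions.

The absolute per-droplet saturated signal is anchored at the *reference* λ
(`reference_lambda_by_strain`), so pools compared at different λ in the same
medium share one capacity and the high-λ pool realizes proportionally
smaller fold changes.  Because the founder-averaged perturbations shrink as
1/√n, raising λ from 5 to 20 narrows the endpoint distribution; with the
default heterogeneity and viability 0.7 the median sd reduction over 100
seeded replicates falls in the 30–55% band.  Well signals are the mean of
10³–10⁴ per-droplet trajectories plus a background offset (5% of capacity by
default) and 1% multiplicative lognormal read noise, on a 10-minute cadence
over 24 h.  Endpoint tables take the per-droplet signals at a chosen time;
droplet area uses a fixed synthetic pixel scale of 1 px = 1 μm².

What the generator does **not** emulate: real micrograph segmentation,
optics, droplet polydispersity or coalescence, spatial gradients within
droplets, and any mechanistic coupling between the droplet's own nutrient
budget and its founder count (the kernel is supplied by the caller, e.g.
from an ODE fit).  Tests passing on synthetic data therefore validate the
statistical pipeline — normalization, fitting, population summaries — not
the biology of any particular dataset.

## Population statistics

Per-droplet endpoints are total intensity per channel divided by droplet
area; bi-culture totals use the green+red sum.  Summaries report the sample
mean and sd (ddof = 1) with a 20-bin histogram by default.  Two-sample
comparisons use Student's pooled-variance t-test (two-tailed), matching the
convention of the experimental analysis this package accompanies; two
zero-variance samples with equal means compare as identical (p = 1).  The
λ-variability metric is the percent sd decrease 100·(1 − sd_high/sd_low).

## Numerical and degenerate-input choices

* Exponents in the logistic are clipped at ±700 to keep `exp` finite.
* Fold-change series divide by the t = 0 biomass; strains seeded at zero
  stay at fold 1 by convention.
* `classify_trend` guards the relative-lag denominator with a 0.1 h floor so
  near-zero reference lags do not blow up the ratio.
* Monotone rate decline tolerates a 2% wiggle between adjacent densities.
* The encapsulation sampler and every generator are driven by
  `numpy.random.default_rng` seeds; per-well streams are spawned from a
  `SeedSequence`, so identical configurations are bit-identical and wells
  are independent.

## Known limitations

* The ODE treats the droplet as well-mixed (diffusion instantaneous), so
  the step-like rate drop between 100 and 125 μm reported experimentally is
  outside its reach, as are contact-dependent exchange and quorum effects.
* The Type 2 signature depends on the observation window by construction;
  sweeping to full saturation turns the same parameter sets into lag
  responses.
* Apparent fitted rates for strongly bootstrapped bi-culture curves can
  exceed μmax — the lag-logistic is an empirical summary of a
  super-exponential curve, not a mechanistic rate estimate.
* The secretion-cost asymmetry (per-amino-acid scale) is a qualitative
  device to orient scenario compositions, not a calibrated quantity.
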