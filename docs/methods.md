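# Methods

## Scope

`marinp` implements a desk-scale analysis chain for marine biogenic ice
nucleation: (1) reduction of droplet-freezing assays to cumulative
ice-nucleating-macromolecule (INM) spectra with chemical normalization,
(2) a classical-nucleation-theory (CNT) forward model with a distribution of
contact angles and its maximum-likelihood estimation, (3) three
ice-nucleating-particle (INP) parametrizations applied to gridded aerosol
fields, and (4) model-observation evaluation with factor-of-N metrics.  A
synthetic-data module generates every input with known ground truth, so the
whole chain is testable offline.

## Assay reduction (Vali spectra)

Droplets of volume V holding Poisson-distributed INMs freeze while cooling;
the cumulative INM concentration of the undiluted sample follows from the
frozen fraction f(T) as n(T) = −ln(1 − f(T)) · dilution / V.  Confidence
bounds are exact Clopper–Pearson binomial intervals on f pushed through the
same transform — chosen because assays have small droplet counts (order 100)
where normal approximations fail.  Fully frozen grid points are reported as
censored lower bounds using f = (k − ½)/k, keeping the spectrum plottable
without infinities.  A paired pure-water background can be subtracted in
concentration space (floored at zero); this is off by default because
comparing against, rather than subtracting, backgrounds is equally common
practice.  Temperatures are kelvin internally; Celsius appears only in CSV
columns.  The default spectrum grid uses 0.5-K bins from 272.15 K down to
238.15 K, resolving the −8 to −25 °C window where marine biogenic INMs act.

Dilution series can be pooled: at each grid temperature the per-dilution
frozen counts are binomial in the same sample concentration, and the pooled
estimate maximizes that joint likelihood (solved by root-finding on the
score; expected-information interval in log concentration).

## CNT forward model

Each nucleation site carries a contact angle θ drawn from a normal
distribution truncated to (0, π] and renormalized (so the site-activation
probability is a proper probability).  The heterogeneous nucleation rate per
site area is

    j_het(T, θ) = A_kin(T) · exp(−[ΔF_diff(T) + f(θ) ΔG_hom(T)] / k_B T),
    f(θ) = (2 + cos θ)(1 − cos θ)² / 4,

with ΔG_hom = (16π/3) σ_iw³ v_ice² / Δμ².  The shipped thermodynamic profile
(`water-ice-cnt-v1`) combines standard literature forms:

* σ_iw(T) = 28.0 + 0.25 (T − 273.15) mJ m⁻² (Pruppacher–Klett),
* Δμ(T) = k_B T ln(p_sat,liq / p_sat,ice) with Murphy–Koop (2005) vapor
  pressures,
* ΔF_diff(T) = k_B · 892 K · T² / (T − 118 K)² (Vogel–Fulcher–Tammann water
  self-diffusion, Zobrist-type),
* A_kin(T) = (k_B T / h) · 10¹⁹ m⁻², validity 235–273.15 K.

Any internally consistent profile serves, because the fitted parameters
(μ_θ, σ_θ, n_max) absorb overall scale; the profile name is recorded with
every fit.  The per-site exposure is a single effective nucleation time
Δt = 60 s per 1-K bin (a 1 K min⁻¹ cooling ramp) over an active site area
a_site = 10⁻¹⁴ m².  These two constants trade off exactly against μ_θ and
n_max, so they are pinned, configurable, and logged.

The site-activation probability P_site(T) integrates
1 − exp(−j_het a_site Δt) over the truncated normal.  The integrand contains
an "activation front" of width k_B T / (ΔG_hom f′(θ*)) ≈ 0.01 rad; the
quadrature is composite 8-point Gauss–Legendre with base panels of ≤ 0.05 rad
over [0, π] plus 40 refinement panels across the front (whose position
depends only on temperature and the thermo profile, not on μ_θ, σ_θ — the
exposure factor is therefore precomputed once per grid and reused for every
likelihood evaluation during fitting).  Verified against a 10⁵-node graded
trapezoid to ~5·10⁻⁹ relative.  For σ_θ below the base panel width the
public entry point adds refinement panels over μ_θ ± 8σ_θ; the fitting path
bounds σ_θ ≥ 0.03 rad instead.  The site density n_m(T) = n_max · P_site(T)
saturates at n_max at deep supercooling — the feature that makes the model
extrapolate safely, unlike log-linear INP fits.

## Fitting

The objective is the exact censored-data likelihood of the observed freezing
temperatures: each droplet contributes the probability of freezing within
its grid interval, f(T_i) − f(T_{i−1}), or of surviving the ramp,
1 − f(T_end), under the forward model f = 1 − exp(−n_m c V / dilution).
(A product of per-bin binomials over *cumulative* counts would double-count
droplets across bins; the interval form is the likelihood those counts
actually have.)  Optimization runs over (μ_θ, ln σ_θ, log₁₀ n_max) with
L-BFGS-B from a 4 × 2 multi-start grid (μ_θ ∈ {1.2, 1.6, 2.0, 2.4} rad ×
log₁₀ n_max offsets {0.3, 1.0} above a Vali-based guess from the coldest
informative bin), with seeded jitter, because the likelihood is multi-modal
in (μ_θ, σ_θ).  Uncertainties come from a seeded parametric bootstrap
(`n_boot`; 200 replicates recommended, disabled by default since it
multiplies fit cost ~200-fold and is unnecessary for point estimates).

On synthetic dilution series (300 droplets × dilutions 1/10/100) the fit
recovers μ_θ to ±0.05 rad and log₁₀ n_max to ±0.05 routinely; the
acceptance experiment demands only ±0.1 rad and ±0.3.

## INP parametrizations

* **Polysaccharide (HSZ25-style)**: N_INP(T) = carbon_fraction · m_poly ·
  n_m,C-TCCHO(T).  The aerosol carries polysaccharide *mass* while the site
  density is per carbohydrate *carbon* mass; the conversion factor defaults
  to 0.40 (glucan-like CH₂O stoichiometry ≈ 0.44, rounded conservatively),
  is configurable, and is surfaced in every output's attributes because it
  is an assumption, not a measurement.
* **Mineral dust (N15-style)**: the same CNT machinery on a per-surface-area
  site budget.  Defaults (μ_θ = 2.1 rad, σ_θ = 0.3 rad, n_s,max = 10¹¹ m⁻²)
  are declared assumptions giving n_s(−15 °C) ≈ 10⁷ m⁻² and n_s(−25 °C) ≈
  1.5·10⁹ m⁻², in the range of desert-dust surface-site observations.
* **Sea spray (M18-style)**: n_s(T) = exp(−0.545 (T − 273.15) + 1.0125) m⁻²,
  validity −27 to −5 °C.  Because the form is unbounded, evaluation outside
  validity raises by default; `clamp=True` pins n_s at the validity edge and
  never extrapolates.

Aerosol surface area comes from lognormal mode mass and number via
d_g = (6M/πρN)^⅓ exp(−1.5 ln²σ_g), S = Nπd_g² exp(2 ln²σ_g).  Mode
geometry defaults (σ_g = 1.59 accumulation / 2.0 coarse; densities
2200 kg m⁻³ sea salt / 2650 kg m⁻³ dust) are declared assumptions standing
in for an external transport-model configuration, and configurable.

## Gridded application and evaluation

Only the lowermost model layer is represented.  Marine polysaccharide mass
is a constant fraction of sea-salt mass (0.5% accumulation / 0.1% coarse by
default; bounding scenarios 0.05% and 0.5% in both modes), which encodes
co-emission with sea spray.  INP fields are computed per time step and
averaged; since the schemes are linear in their aerosol proxy at fixed
temperature, the time mean commutes with the scheme.  Sea-salt-derived INP
(polysaccharide and sea-spray schemes) is zeroed over land; dust INP is kept
everywhere.  Default activation temperatures are −15…−20 °C at 1-K spacing
(so any observation in the evaluation window is within the 0.5-K matching
tolerance of a level) plus −23 and −25 °C for share maps.

Evaluation pairs each observation with the nearest grid cell by great-circle
distance and the nearest evaluated temperature within 0.5 K (observations
farther from a level are skipped and counted).  Annual-mean model values are
compared with instantaneous observations deliberately: short-term aerosol
variability averages out of remote-marine INP statistics.  FAC-N is the
fraction of pairs with max(model/obs, obs/model) ≤ N; pairs with a zero on
either side are excluded and reported.  The improvement fraction

    F = (FAC10_{dust+poly} − FAC10_{dust}) / (FAC10_{dust+seaspray} − FAC10_{dust})

measures how much of the sea-spray scheme's factor-10 gain the
polysaccharide scheme reproduces; it may exceed 1, and is flagged undefined
when the denominator is ≤ 0.

## Synthetic data: what it emulates and what it does not

The generator produces the four input kinds with known truth under one
master seed split into named substreams (no global random state).

* **Assays**: each droplet holds Poisson(n_max c V / dilution) INMs with
  truncated-normal contact angles; cooling proceeds in 1-K steps at
  1 K min⁻¹, and an INM nucleates in a step with probability
  1 − exp(−j_het a_site Δt_step).  Because Δt_step equals the model's Δt and
  j_het grows several e-folds per kelvin, the model's single-exposure
  activation matches the simulator's cumulative hazard to ~1% (an
  equivalent temperature shift below 0.01 K).  The analytic oracle used in
  tests integrates the exact cumulative hazard, with the small-θ tail (the
  rare near-perfect nuclei behind sporadic warm freezing events) integrated
  explicitly.
* **Default organism truth**: μ_θ = 1.70 rad, σ_θ = 0.28 rad, n_max =
  3·10¹⁰ per g C, culture C-TCCHO = 5 mg C L⁻¹ — freezing onset just below
  −8 °C and n_m,C-TCCHO(−15 °C) ≈ 1.5·10⁸ per g C, in the observed range
  for marine microbial INMs.
* **Fields**: a 24 × 12-cell globe at 6-hourly resolution for 30 model days
  (the hourly × 1-year pathway is supported for real data; the desk default
  keeps the end-to-end run in seconds).  Sea salt peaks over mid-latitude
  storm tracks over idealized ocean; dust decays from two northern sources
  and one weak southern source over a 2·10⁻¹² kg m⁻³ background, making the
  southern ocean dust-poor (hemispheric asymmetry).  Mode numbers follow
  from masses through fixed median diameters, so surface areas invert to
  the same geometry.  Not emulated: meteorology, seasonality, emission
  physics, vertical structure, realistic coastlines.
* **Observations**: ocean cells and activation temperatures uniform in
  −20…−15 °C; observed INP = truth × exp(ε), ε ~ N(0, ln 3).  The noise-free
  truth uses the nearest evaluated temperature level, consistent with the
  matching rule, so the zero-noise closure is exact.

Passing tests therefore demonstrate internal consistency of the estimators
and schemes under Poisson/CNT physics and lognormal observation noise —
not fidelity to any particular ocean basin, aerosol climatology, or field
campaign.

## Numerical choices and degenerate inputs

* Frozen fraction exactly 1 → censored lower bound, never infinite.
* Zero site budget (n_max = 0) is allowed and yields identically zero
  spectra and INP.
* Chemical potential difference ≤ 0 (no supercooling) → j_het = 0.
* Quadrature failure (non-finite or out-of-[0,1] probability) raises with
  the offending parameters rather than clipping silently.
* FAC metrics with no valid pairs return NaN with a warning.
* Share maps mask (NaN) cells where both INP components are zero.
* All random draws flow through `numpy.random.Generator` substreams keyed
  by (seed, stream id); identical seeds are bit-reproducible.

## Known limitations

* Single-exposure kinetics: no isothermal (time-resolved) freezing, no
  deposition/contact modes.
* The per-site picture cannot distinguish one-site-per-macromolecule from
  many-sites-per-particle; n_max simply rescales under reinterpretation.
* The fixed-fraction polysaccharide scenario has no spatiotemporal
  variability and no dynamic emission; bounding scenarios quantify only the
  constant-fraction uncertainty.
* The binomial-band Monte-Carlo check uses exact 95% intervals, so across
  reseeds the per-bin coverage fluctuates around its nominal level; the
  documented fixed-seed condition is the reference experiment.
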