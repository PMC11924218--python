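# marinp

Marine biogenic ice nucleation, end to end: from droplet-freezing assays of
microbial cultures to global maps of ice-nucleating-particle (INP)
concentrations and their comparison with field observations.

Clouds over remote oceans freeze through heterogeneous ice nucleation, and
the responsible particles are scarce: mineral dust transported over long
distances, and biogenic material ejected with sea spray.  A growing body of
evidence points to polysaccharides — produced by marine fungi, protists and
algae — as the ice-nucleating macromolecules (INMs) behind much of the
marine biogenic signal.  `marinp` provides the analysis chain needed to make
that case quantitatively and to use it in models:

1. **`assay_spectra`** — reduce droplet-freezing assays to cumulative INM
   spectra n(T) = −ln(1 − f(T)) · dilution / V (Vali method, exact binomial
   confidence bounds), normalize them per carbohydrate carbon mass
   (n_m,C-TCCHO), and quantify treatment effects (filtration, heating,
   hydrolysis).
2. **`cnt_model` / `cnt_fitting`** — a classical-nucleation-theory forward
   model in which each site carries a contact angle θ from a truncated
   normal distribution; the rate per site area is
   j_het = A_kin exp(−[ΔF_diff + f(θ) ΔG_hom]/k_B T) with the spherical-cap
   factor f(θ) = (2 + cos θ)(1 − cos θ)²/4, and the site density
   n_m(T) = n_max ∫ p(θ) [1 − e^{−j a Δt}] dθ saturates at n_max instead of
   extrapolating without bound.  Parameters (μ_θ, σ_θ, n_max) are estimated
   by exact censored-data maximum likelihood from dilution series.
3. **`inp_parametrizations` / `global_inp`** — apply three INP schemes to
   gridded aerosol fields: polysaccharide mass × fitted n_m,C-TCCHO
   (HSZ25-style), mineral-dust surface area × CNT surface-site density
   (N15-style), and sea-spray surface area × exponential site density
   (M18-style), with polysaccharide mass taken as a constant fraction of
   sea-salt mass (0.5% accumulation / 0.1% coarse; 0.05–0.5% bounds).
4. **`evaluation`** — match modeled fields to observation records and score
   FAC2/FAC10 (fraction of pairs within a factor 2/10) and the improvement
   fraction F = (FAC10_dust+poly − FAC10_dust)/(FAC10_dust+seaspray −
   FAC10_dust).
5. **`synthetic_data`** — seeded generators for all four input kinds
   (assays, chemistry, aerosol fields, observations) with known ground
   truth, so the whole chain runs and is tested without any downloads.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
import math
from marinp import (SimConfig, simulate_assay, fit_cnt, generate_fields,
                    generate_observations, inp_fields, polysaccharide_share,
                    evaluate, ScenarioConfig)

cfg = SimConfig(seed=7)                      # synthetic study conditions
chem = cfg.chemistry()                       # culture: 5 mg C-TCCHO per litre
assays = [simulate_assay(cfg, chem, dilution=d, stream_key=10 + i)
          for i, d in enumerate(cfg.dilutions)]
fit = fit_cnt(assays, chem, seed=cfg.seed)   # CNT fit of the dilution series
print(f"fitted: mu_theta={fit.params.mu_theta:.3f} rad, "
      f"sigma_theta={fit.params.sigma_theta:.3f} rad, "
      f"log10 n_max={math.log10(fit.params.n_max):.2f} per g C")

fields = generate_fields(cfg)                # synthetic aerosol globe
scen = ScenarioConfig()                      # 0.5% / 0.1% polysaccharide
inp = inp_fields(fields, scen, fit.params)   # dust + polysaccharide + seaspray
share = polysaccharide_share(inp, T=273.15 - 15.0)
print(f"polysaccharide share at -15 C: max {float(share.max()):.1f}%, "
      f"ocean mean {float(share.mean()):.1f}%")

obs = generate_observations(fields, scen, cfg,
                            inp=inp_fields(fields, scen, cfg.true_params))
print(evaluate(obs, inp).summary())
```

prints

```
fitted: mu_theta=1.704 rad, sigma_theta=0.278 rad, log10 n_max=10.45 per g C
polysaccharide share at -15 C: max 96.3%, ocean mean 43.7%
pairs: 200 in window [-20.0, -15.0] C (scenario n/a)
  N15        FAC2 = 0.285  FAC10 = 0.835
  N15+M18    FAC2 = 0.390  FAC10 = 0.935
  N15+HSZ25  FAC2 = 0.445  FAC10 = 0.960
  improvement fraction (polysaccharide share of the M18 FAC10 gain): 1.250
```

Reading this: the fit recovers the generating contact-angle distribution of
the synthetic organism (truth: 1.70 rad, 0.28 rad, log₁₀ n_max = 10.48); on
the constructed globe, polysaccharides dominate the dust + polysaccharide
INP budget over the sea-salt-rich, dust-poor southern ocean at −15 °C; and
against observations noised by a factor of 3 (lognormal), adding the
polysaccharide scheme raises the fraction of model values within a factor
of 10 of the observations from 0.835 (dust alone) to 0.960 — at least as
much gain as the sea-spray-surface scheme provides (improvement fraction
1.25; values above 1 mean the polysaccharide scheme explains more than all
of that gain).

The same chain is available from the shell:

```sh
marinp simulate --seed 7 --out demo/
marinp spectra  --assays demo/assays.csv --chemistry demo/chemistry.csv \
                --basis c_tccho --out demo/spectra.csv
marinp fit      --assays demo/assays.csv --chemistry demo/chemistry.csv \
                --seed 7 --out demo/params.yaml
marinp apply    --fields demo/fields.nc --params demo/hsz25.yaml --out demo/inp.nc
marinp evaluate --obs demo/observations.csv --fields demo/inp.nc
```

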