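# quailtherm

Does body size and shape actually change what thermoregulation costs a bird?
`quailtherm` implements the full inference chain of a temperature-manipulation
experiment on Japanese quail (*Coturnix japonica*) that asks exactly that:
birds reared cold (10 °C), mild (20 °C) or warm (30 °C) across three egg
batches, measured weekly for body mass, tarsus and bill length, and run
through flow-through respirometry at 10/20/30/40 °C as juveniles and adults.
It is aimed at ecophysiologists and quantitative ecologists who want to
reproduce, probe, or reuse this style of analysis on their own data.

The chain, end to end:

1. **Respirometry reduction** — the most stable 2 min of each gas trace is
   reduced to oxygen consumption `VO₂ = FR·(FiO₂ − FeO₂)/(1 − FiO₂)`,
   evaporative water loss, metabolic heat production (20 J · mL O₂⁻¹),
   evaporative heat loss (2406 J · mL H₂O⁻¹) and evaporative cooling
   efficiency ECE = EHL/MHP. Resting metabolism is relativised per bird as
   the fold change from 30 °C (thermoneutrality).
2. **Metabolic slopes** — below thermoneutrality, a Bayesian fixed-intercept
   random-slope model `RM_ij ~ 1 + (β₁ + v_j)·(Ta − pivot) + ε_ij` with
   temperature-specific residual SDs; each bird's thermoregulatory-cost
   phenotype is its slope β₁ + v_j. Above thermoneutrality the slope is the
   two-point computation (RM(40) − 1)/10.
3. **Repeatability** — conditional repeatability
   R(ΔT) = σ_v²ΔT²/(σ_v²ΔT² + σ_ε²), tested against a permutation null in
   which individual identities are scrambled among measurements.
4. **Path analyses** — four linked regressions (mass ← rearing;
   tarsus, bill ← rearing + mass; slope/ECE ← rearing + mass + tarsus +
   bill) with egg-batch intercepts, the study's full prior ledger,
   Student-t errors for heat slopes, Savage-Dickey Bayes factors
   (BF10 = prior/posterior density at 0) per coefficient, partial R²,
   posterior predictions, Cohen's D effect fields over the bivariate
   (mass, tarsus) phenotype distribution with rarity fractions, allometry,
   and a simulated selective-disappearance contrast.
5. **Growth** — hierarchical Gompertz models `a·exp(−b·exp(−c·t))` with
   rearing effects on (a, b, c), individual and batch effects, a within-week
   standardised mass covariate for the appendages, and residual SD growing
   as τ₀ + τ₁·ln(t+1); treatment contrasts with Bayes factors.

Posterior sampling is an ensemble MCMC (emcee, differential-evolution moves)
behind a statsmodels-style surface: a Model class built from data and a
spec, whose `fit()` returns a Results object with draws, quantile-interval
summaries, R-hat/ESS diagnostics and a `summary()` table. Random effects
that enter linearly are marginalised analytically, so fits take seconds.
A synthetic-data generator reproduces the experiment's design with recorded
ground truth for every latent quantity. See `docs/methods.md` for the
models, priors and design choices.

## Worked example

```python
from quailtherm import (
    GeneratorConfig, generate_population, relativize,
    ColdSlopeModel, default_slope_spec,
    GompertzModel, default_gompertz_spec, treatment_contrast,
)

config = GeneratorConfig(seed=42)          # 45 birds per rearing treatment
data, truth = generate_population(config)

records = [r for r in data.respirometry_records() if r.age_class == "adult"]
profiles, _ = relativize(records)
fit = ColdSlopeModel(profiles, default_slope_spec("adult")).fit(
    chains=2, draws=800, seed=42
)
print(fit.summary().head(2).to_string(index=False))
rep = fit.repeatability()
print(f"conditional repeatability = {rep.median:.3f} "
      f"[95%: {rep.ci95[0]:.3f}, {rep.ci95[1]:.3f}]")

growth = data.morphometry.merge(data.individuals[["id", "batch", "rearing"]], on="id")
gfit = GompertzModel(growth, default_gompertz_spec("mass")).fit(
    chains=2, draws=800, seed=42
)
contrast, _ = treatment_contrast(gfit, "a", ("warm", "cold"))
print(f"warm - cold asymptotic mass: {contrast.median:.2f} g "
      f"[95%: {contrast.ci95[0]:.2f}, {contrast.ci95[1]:.2f}], {contrast.bf.display}")
```

prints

```
parameter    median       q25       q75      q2.5     q97.5     rhat  ess_ratio
    beta1 -0.019082 -0.019666 -0.018492 -0.020805 -0.017381 1.000109   0.915598
  sigma_v  0.003872  0.002294  0.005428  0.000356  0.007965 1.002920   0.891213
conditional repeatability = 0.066 [95%: 0.001, 0.258]
warm - cold asymptotic mass: -22.25 g [95%: -26.88, -17.75], BF > 1000
```

Reading the output: adults raise resting metabolism ≈ 1.9% per °C of
cooling (the generator's population slope is −0.018 per °C), with individual
slopes spread σ_v ≈ 0.004 around it; repeatability is the share of variance
in relative metabolism due to those stable individual differences. The
warm-reared birds plateau ≈ 22 g lighter than cold-reared ones in this
realisation — the generating population contrast is −13 g, and with
individual asymptote SD of 25 g a single 45-bird-per-group study drifts
around it (this seed's realised contrast is −20.8 g, inside the interval).

The command line mirrors the pipeline stages
(`quailtherm simulate | reduce | slopes | paths | growth | report`); `report`
runs everything from one JSON config and writes coefficient tables,
repeatability and effect-field reports, growth contrasts and a provenance
manifest (version, seed, config hash).

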