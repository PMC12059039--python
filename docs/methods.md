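# Methods

This note documents the models implemented in `quailtherm`, the choices made
where the analysis design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Respirometry reduction

Flow-through traces are reduced over the most stable 2 minutes of a
recording. "Most stable" is defined as the contiguous window minimising the
rolling standard deviation of the excurrent O2 channel, ties breaking to the
earliest start; the same window supplies the water-vapour means so VO2 and
evaporative water loss (EWL) describe the same behavioural state. With water
vapour and CO2 scrubbed upstream of the O2 analyser, oxygen consumption is

    VO2 = FR (FiO2 - FeO2) / (1 - FiO2)        [mL O2 min^-1, FR in mL min^-1 STPD]

EWL converts the vapour volume flow FR (WVPe - WVPi)/(BP - WVPe) to liquid
water via 18.016 g mol^-1 / 22 414 mL mol^-1. Heat production uses 20 J per
mL O2; evaporative heat loss uses 2406 J per mL water; evaporative cooling
efficiency (ECE) is their ratio EHL/MHP, undefined when MHP is zero.
Negative apparent consumption (FeO2 > FiO2) is returned with a warning, not
clamped, so instrument drift stays visible. When initial and terminal
baseline segments are supplied, incurrent FiO2 is drift-corrected by linear
interpolation between the two baseline means.

Resting metabolism is relativised per individual and age class as the fold
change from the 30 degC (thermoneutral) measurement, so every profile equals
exactly 1 at 30 degC and individual differences are confined to the
*response* to temperature. Individuals without a thermoneutral measurement
are excluded with a logged reason.

## Cold metabolic slopes

Relative metabolism below thermoneutrality follows a fixed-intercept
random-slope regression through the pivot (30 degC for juveniles; 24 degC
for adults, whose thermoneutral zone extends to ~24 degC):

    RM_ij = 1 + (beta1 + v_j)(Ta_ij - pivot) + eps_ij,
    v_j ~ N(0, sigma_v^2),   eps_ij ~ N(0, sigma_eps(Ta)^2)

Priors follow the study's ledger: beta1 ~ skew-normal(-0.018, 0.02, -2.5);
sigma_v ~ Exponential(2.5); log sigma_eps at the coldest temperature ~
skew-normal(-0.2, 1.0, -5); the drop in log SD from 10 to 20 degC ~
N(0.25, 0.25) (variability shrinks toward thermoneutrality). Exact-pivot
rows have identically unit response and zero residual; they carry no
likelihood information and are excluded (including them with a floored SD
would make the likelihood improper). Residual SDs are floored at 1e-5
fold-change units so degenerate noise-free inputs stay proper.

Because v_j enters the mean linearly, it is marginalised analytically: each
individual's measurements are jointly normal with covariance
`diag(sigma_eps^2) + sigma_v^2 x x'`, handled by a rank-one Woodbury/
Sherman-Morrison update. MCMC then explores only (beta1, sigma_v, residual
SDs); v_j posterior draws are recovered exactly afterwards from their
conjugate normal conditional, so per-individual slope draws are
`beta1 + v_j` by construction.

Conditional repeatability at temperature offset dT is

    R(dT) = sigma_v^2 dT^2 / (sigma_v^2 dT^2 + sigma_eps(T)^2),

reported per measured sub-thermoneutral temperature and, as the headline
number, averaged over them (the appropriate dT for a single summary is not
uniquely defined; per-temperature values are always exposed). The
permutation null refits the model after scrambling individual identities
among measurements; labels are permuted within temperature, which preserves
the design (one measurement per pseudo-individual per temperature) and every
marginal distribution while destroying within-individual association. The
comparison reports Pr(R_true > R_null) over all cross pairs of draws plus a
Savage-Dickey Bayes factor on the true-minus-null difference under a default
N(0, 0.5) difference prior (the study's test priors are not published in the
main text).

Above thermoneutrality only 30 and 40 degC were measured, so the heat slope
is computed directly: (RM(40) - 1)/10 per degC.

## Bayesian machinery

Models are named parameter blocks with explicit priors plus a vectorised
log-likelihood. Sampling uses an affine-invariant ensemble (emcee) with a
0.8/0.2 mixture of differential-evolution and DE-snooker moves, which mixes
several-fold faster than stretch moves on these correlated posteriors.
Walkers are grouped into chains; after burn-in the chain is thinned by the
estimated integrated autocorrelation time, and thinning is doubled (reusing
the accumulated chain) until the effective-sample-size gate is met or a cap
is reached. A fit is flagged unhealthy when rank-normalised R-hat leaves
[0.99, 1.05] or ESS/N falls below 0.75 for any block. Draws are reproducible
from the seed; the full RandomState state tuple is installed in the sampler
(its setter silently ignores anything else).

Scale parameters with well-identified posteriors (residual SDs, individual
SD, Student-t df) are sampled on the log scale with the Jacobian correction
(`log-sample` transform), removing the zero boundary; group-level (egg
batch) SDs, whose posteriors hug zero, are sampled on the natural scale with
non-centred effects (u = sd * z, z ~ N(0,1)) to avoid funnels. Priors stated
by the study on the log of a quantity use the `log` transform (prior density
on the log value).

Savage-Dickey Bayes factors: BF10 = prior density at 0 / posterior density
at 0, the posterior density estimated by a Gaussian KDE with Silverman
bandwidth (moment-matched normal fallback for degenerate draws). Following
common reporting practice, BF > 1000 is truncated and displayed as
"BF > 1000"; a BF >= 3 is read as moderate support. Posterior summaries are
medians with 50% and 95% central quantile intervals, which are robust to the
skew typical of variance parameters.

Posterior-prediction Cohen's D between two states is computed per draw as
(A - B)/SD_ref, where SD_ref is the posterior-predictive SD of the response:
per draw, the spread of fitted values across the analysed individuals
combined with the residual variance (times nu/(nu-2) for Student-t errors).

## Path analyses

Four linked regressions with uncorrelated residuals (hence fitted equation
by equation, which is exact): mass on rearing; tarsus and bill on rearing
and mass; the terminal response (cold slope, heat slope, or ECE) on rearing,
mass, tarsus and bill. Cold and warm rearing are 0/1 indicators with mild
(20 degC) rearing as the reference; continuous predictors are mean-centred;
slope responses are mean-centred while ECE stays on its natural scale (its
intercept priors, N(0.5, 0.2)/N(0.75, 0.2), are clearly on that scale). Egg
batch enters every equation as an exchangeable intercept. Error families per
the study: normal for cold slopes and ECE, Student-t with estimated df for
heat slopes (df priors Gamma(5,1) juveniles, Gamma(10,1) adults), with
batch-specific log-scale residual SDs for juvenile heat and ECE models. The
full prior ledger is reproduced in `quailtherm.paths.default_path_spec`.

Derived quantities:

- **Partial R^2** of a predictor, per draw: the proportional reduction in
  residual variance when the predictor's contribution is added back,
  (V_without - V_with)/V_without, floored at zero — matching reported
  intervals that truncate at 0. This is a posterior quantity; with a weak
  signal its median can sit well above zero purely through coefficient
  uncertainty, so it is read alongside the Bayes factor.
- **Predictions** at phenotype states in SD units of the analysis subset
  (the same individuals entering the fit), other predictors held at their
  means; at the all-mean state the prediction is the intercept draws
  exactly.
- **Effect fields**: mean Cohen's D of each (mass, tarsus) grid node versus
  the modal phenotype (the mean of a bivariate normal fitted to the analysis
  subset), holding bill and rearing at their means. For a linear terminal
  equation the mean-D surface is linear with coefficients E[beta/SD_ref], so
  D is evaluated exactly anywhere. Rarity fractions integrate the fitted
  bivariate normal (trapezoidal rule on the grid, normalised over the grid)
  over the region where D exceeds a threshold in the *cost* direction —
  higher response = higher thermoregulatory cost; thresholds 0.5 (moderate)
  and 0.8 (large) by default. The study phrases costs as "D >= -0.5" with an
  inverted sign convention; here the signed cost direction is explicit and a
  `direction="benefit"` flag flips it.
- **Allometry**: the mass coefficient of the tarsus or bill equation, in mm
  per g, with its Savage-Dickey BF.
- **Selective disappearance**: individuals whose phenotype has mean D at or
  above the threshold are removed, the allometry refitted, and the change in
  slope (with - without) reported as mean +/- SD with a BF under a
  N(0, sqrt(2) * prior scale) difference prior. If nothing is removed the
  contrast is exactly zero; removal that empties a rearing group is an
  error.

## Gompertz growth

Each trait follows a * exp(-b * exp(-c * t)) in age t (weeks from hatching,
t = 0 within 12 h of hatch), with each of (a, b, c) linear in the rearing
indicators plus an exchangeable egg-batch effect, an individual intercept
(marginalised analytically, as in the slope model), and for the appendages a
body-mass covariate standardised within measurement week. The covariate is
per within-week SD because the study's informative prior for it
(skew-normal(0.5, 0.15, 5)) is only dimensionally sensible on that scale
(0.5 mm per SD ~ 0.02-0.03 mm per g); with raw grams that prior would
swamp the data. Residual SD grows with age:

    sd(t) = tau0 + tau1 * ln(t + 1)

with tau0 constrained positive via a prior on its log. The additive-SD link
is the default reading of the study's error equation; a fully log-linear
alternative sits behind `sigma_link="log-linear"`. Growth rates are
constrained non-negative (no negative growth). Treatment contrasts of a
parameter (e.g. warm-minus-cold asymptote) are per-draw differences with a
Savage-Dickey BF under the normal prior implied by the two rearing-effect
priors. The full prior ledger is in `quailtherm.growth.default_gompertz_spec`.

## Synthetic studies

The generator reproduces the experiment's structure: 3 egg batches x 3
rearing treatments (10/20/30 degC), default 15 birds per treatment x batch
(45 per treatment, 135 total — the study's scale); weekly mass from week 0
to 8 and appendages at weeks 0-3 and 8; respirometry at 10/20/30/40 degC as
juveniles (week 3) and adults (week 8), reduced to absolute VO2 so the
package's own relativisation is exercised. Ground truth (individual slopes,
growth intercepts, batch effects) is recorded for recovery scoring, and the
same config + seed is bit-identical.

Defaults are the study's conditions where printed: Gompertz scales (250 g /
37.5 mm / 15.7 mm asymptotes; warm-cold contrasts -13 g, +0.66 mm,
+0.44 mm, mass rate +0.06 per week), cold slope -0.018 per degC with
individual SD 0.005 and residual SDs 0.15/0.10 at 10/20 degC, heat-slope
morphometry coefficients 3e-4 (mass), -2.4e-3 (tarsus), -5.6e-3 (bill) for
adults and the printed juvenile values, tarsus allometry 0.029 mm/g, and ECE
coefficients as printed. Where the study reports no value, defaults were
chosen once to make its summary statistics plausible: individual trait SDs
sized to the printed CVs (mass 13.3%, tarsus 6.4%, bill 8.7%); heat-slope
residual scale 0.035 and ECE 0.12 so morphometry explains a few percent of
response variance (printed partial R^2 ~ 0.05) and moderate-cost phenotypes
are rare; heat residuals Student-t (df 10 adults, 5 juveniles — the centres
of the study's df priors) because the study reports heavy-tailed heat
slopes.

What the generator does **not** emulate: attrition/removal of distressed
birds, sex effects, body-temperature responses, baseline drift in the
deposited (already reduced) data, batch 3's restricted temperature schedule,
and measurement rounding. Passing recovery tests therefore demonstrate that
the estimators are calibrated under the study's design and noise scales, not
that every idiosyncrasy of the real data is handled.

A second generator synthesises raw gas traces around target VO2/EWL values
with a designated low-noise segment, for end-to-end tests of the trace
reduction; with zero noise the reduction recovers the targets exactly.

## Numerical and testing choices

- Ensemble sizes: >= max(2*dim + 2, 64) walkers; burn-in >= 20-25 steps per
  dimension; thinning by ~1.25x the estimated autocorrelation time with
  ESS-driven doubling (cap 160; 400 for batch-effect growth models, whose
  batch-scale posteriors mix slowest).
- Degenerate inputs: residual-SD floors (1e-5 slope model, 1e-8 path
  equations, 1e-6 growth) keep likelihoods proper on noise-free data;
  non-finite log-densities are rejected, never propagated.
- Tie-breaks: stable-window ties resolve to the earliest start within
  1e-14 relative numerical jitter.
- Reported problem sizes: recovery tests use 20 replicate studies at 45-50
  individuals with 2 chains x 400-600 retained draws per fit; the
  acceptance script runs one full study at 135 birds with 2 chains x 800
  draws and 5 identity scrambles. These sizes give stable pass/fail
  behaviour while keeping a full run in minutes on one CPU.
- Known limitations: the equation-by-equation path fit is exact only under
  the stated uncorrelated-residual assumption; repeatability is defined for
  the random-slope structure (no random intercepts below the pivot, which
  the fixed-intercept relativisation removes by construction); the
  permutation null pools repeatability draws across scrambled refits rather
  than re-deriving a small-sample null distribution per scramble; BF values
  above 1000 are reported as a bound, not an estimate.
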