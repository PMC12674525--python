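# Methods

## Model

`isodiet` estimates diet-source consumption proportions from bulk-collagen
δ¹³C and δ¹⁵N, jointly for consumers measured once (bone) and consumers
measured repeatedly (sequential dentine slices of one tooth).

Indices: subgroup g = 1…G, source k = 1…K, tracer t ∈ {δ¹³C, δ¹⁵N},
individual i, slice j.

**Mean structure.** Each measurement is conditionally normal around the
concentration-weighted, TEF-adjusted source average

    m_{g,t} = Σ_k p_{g,k} c_{k,e(t)} (μ_{k,t} + λ_{k,t}) / Σ_k p_{g,k} c_{k,e(t)}

with carbon concentration weighting δ¹³C and nitrogen weighting δ¹⁵N.
Concentration weighting matters mainly through plants: their nitrogen
content is an order of magnitude below animal tissue, so a sizeable plant
proportion moves δ¹⁵N far less than δ¹³C.

**Error structure.** Bone: y = m + a_i, a_i ~ N(0, σ_ind²). Dentine slice:
y_ij = m + a_i + e_ij, e_ij ~ N(0, σ_samp²), with a_i shared across the
tooth's slices and σ_ind common to bone and dentine. The marginal law of a
tooth's J slices is multivariate normal with compound-symmetry covariance
σ_ind²·11ᵀ + σ_samp²·I; the implementation evaluates the closed form

    −J/2·log 2π − (J−1)/2·log v − ½·log(v + J·u) − SS_w/(2v) − J(ȳ−m)²/(2(v+Ju))

(u = σ_ind², v = σ_samp², SS_w the within-tooth sum of squares), which
equals the integral of the slice likelihood over the latent a_i — the test
suite checks this identity against adaptive Gauss–Hermite quadrature to
1e-8. Tracers are conditionally independent given the parameters; slices
within a tooth are exchangeable (no within-tooth time trend is modeled).

**Source model.** Reference specimens of source k are N(μ_{k,t}, τ_{k,t})
per tracer; μ and τ are estimated jointly with everything else, so source
uncertainty propagates into the proportions through the posterior.

**Priors.** Proportions: Dirichlet(α) per subgroup, α = (1,…,1) by
default — uniform over the simplex, hence marginally Beta(1, K−1) per
component. This is deliberately the only non-informative block. Defaults
for the rest are data-scaled and config-overridable:

| parameter | prior | default scale | rationale |
|---|---|---|---|
| μ_{k,t} | Normal | source sample mean, SD/√n (floored at 0.25‰/√n) | standard-error-sized prior keeps μ anchored to its reference samples |
| τ_{k,t} | half-Normal | pooled within-source sample SD per tracer | weakly informative, right order of magnitude |
| σ_ind, σ_samp (per tracer) | half-Normal | pooled consumer SD per tracer (floor 0.25‰) | total consumer spread upper-bounds either component |

TEF defaults: λ = +1‰ (δ¹³C), +3‰ (δ¹⁵N) per trophic step, treated as
fixed (`tef_mode="fixed"`); `"normal_uncertain"` folds the configured TEF
SDs into the consumer variance through the squared mixture weights.
Propagation of source variance τ² into the consumer variance
(`propagate_source_variance`) is off by default — the hierarchical error
statement lists only individual and sample effects — with the switch
provided for classic fully-propagated mixing-model behavior.

Concentrations c_{k,e} are required configuration. The shipped defaults
(animal sources ≈ 45–47% C / 13–14% N; C₃ plants 42% C / 2.5% N) are
field-typical dry-tissue values chosen once for the synthetic scenario.

## Sampling

The joint posterior is sampled over an unconstrained parameterization:
additive log-ratio (softmax) coordinates for each proportion row with the
Dirichlet density carried through the change of variables (log-Jacobian
Σ_k log p_k per row), and log transforms for all scale parameters. The
sampler is differential-evolution ensemble MCMC (80% DE moves, 20%
snooker moves) with a vectorized log-posterior; `chains` independent
ensembles run from seeds derived from the master seed, initialized at
prior medians with seed-controlled jitter.

Diagnostics: split-R̂ treats each independent ensemble as one chain whose
draws pool its walkers step-major, so it measures agreement between
independent runs and first/second-half drift; effective sample size is
computed on per-walker trajectories, which carry the sampler's true
autocorrelation (per-walker integrated autocorrelation times are ~150
steps on the default joint model, so walker-trajectory R̂ would conflate
slow per-walker mixing with non-convergence). Parameters are flagged at
R̂ > 1.01 or bulk ESS < 100; the CLI's run gate fails at R̂ > 1.05.
Defaults are 4 ensembles × 1000 warmup + 1000 retained steps; the
convergence test in the suite uses 4 × (4000 + 2000) steps, which brings
every proportion's split-R̂ under 1.01 on the default synthetic fit.

Degenerate inputs: all proportion mass on (numerically) zero-concentration
sources raises a degenerate-input error; σ_samp = 0 with unequal slices
yields −∞ log-density rather than an exception; non-finite log-posterior
at initialization raises an informative initialization error after
seeded re-jittering attempts.

## Data handling

Quality control keeps records with %C > 13, %N > 5 and atomic C/N in
[2.9, 3.6] (the C/N bounds read as inclusive, the content thresholds as
strict); an optional collagen-yield threshold applies only when configured
and present, since dentine slices usually lack yields. Missing or
non-numeric QC fields reject the record with a reason rather than raising.
Modern plant δ¹³C reference values are Suess-corrected by a configurable
shift (+2‰ for 2010-era material); both raw and shifted values can be kept
since published source means are sometimes already corrected.

Dentine slices are assigned an age category through an anatomical
(tooth type, segment) → age-interval grid; the category is the one
containing the segment's age midpoint — a deterministic surrogate for
anatomical age alignment. Where the anatomical literature prints
alternative bounds ("9/10"), the first value is used. Records in
categories entirely below the exclusion age (default 5 years) are dropped,
bone and dentine alike, to avoid breastfeeding-elevated δ¹⁵N.

## Posterior reporting

Proportion margins are summarized by quartiles (linear interpolation
between order statistics), the KDE argmax as mode, and 50%/95% HPD
regions. Densities on [0, 1] use a Gaussian KDE with Silverman bandwidth
and reflection about both boundaries (images at −x and 2−x), which
restores full density at the edges where a plain KDE halves it; the
estimate agrees with the unreflected KDE more than ~5 bandwidths into the
interior (closer than that, Gaussian tail mass from the images is
non-negligible by construction). HPD regions come from bisection on the
density level with mass computed by trapezoid rule including linearly
interpolated partial cells on a 512-point grid; multimodal margins may
honestly report several disjoint intervals and none are merged. If all
draws coincide, an epsilon bandwidth (10⁻³ of the support) is substituted
and the estimate flagged degenerate.

## Synthetic data

The generator mirrors the model exactly — that is its point and its
limitation. Default scenario: four sources with normal tracer laws seeded
from published shellmound fauna summaries (marine fish −12.2 ± 2.6 /
12.4 ± 2.1‰; freshwater fish −23.0 ± 2.1 / 9.8 ± 1.9‰; terrestrial
animals −19.9 ± 2.5 / 8.7 ± 2.9‰; C₃ plants −27.2 ± 3.0 / 1.1 ± 2.0‰
with δ¹³C already Suess-shifted), TEFs (+1‰, +3‰), σ_ind = (0.7, 0.8)‰
and σ_samp = (0.4, 0.5)‰ chosen at the scale of observed human
between-individual and within-tooth spreads. Age categories 5–9, 9–15 and
adults with a paper-scale design (subadult subgroups: 3 bone + 4 teeth × 8
slices; adults: 16 bone). The two-subgroup recovery design uses 15 bone +
3 teeth × 8 slices per subgroup. Each replicate derives its RNG stream
from the master seed by fixed offsets and all outputs carry seed metadata.

What passing synthetic tests does **not** show: robustness to
non-normal source distributions, tracer correlation, within-tooth dietary
trends (weaning curves), isotopic routing, or mis-specified TEFs and
concentrations — real-data inference is conditional on those choices, and
sources with overlapping isotopic signatures (here freshwater fish vs
terrestrial animals) remain only weakly separable no matter the sampler.

## Validation scales

The recovery experiment reports central 95% credible-interval coverage
and the median absolute error of posterior medians over 30 replicates at
the two-subgroup design, using 2 ensembles × (500 + 300) steps per fit —
enough effective draws (~hundreds) for stable medians and interval
endpoints while keeping the full experiment at desk scale. The
reduced-model oracle comparison holds source means and error SDs fixed so
that a dense-grid quadrature posterior over the single free proportion is
exact; ten randomized instances are compared on posterior means and
5%/95% quantiles.

## Known limitations

- Slices are exchangeable within a tooth; serial (age-trend) structure in
  a dentine profile is averaged into the individual effect.
- The marginal likelihood approach assumes normal errors on the δ scale;
  heavy-tailed measurement contamination will inflate σ estimates.
- With K sources and only two tracers (K > T + 1), proportions are only
  partially identified and the Dirichlet prior matters; margins can stay
  close to Beta(1, K−1) for weakly informative subgroups. Aggregating
  posterior proportions of isotopically similar sources is the sensible
  reporting remedy.
- Per-site fits are separate model runs; no hierarchical pooling across
  sites is implemented.
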