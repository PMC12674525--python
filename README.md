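# isodiet

Bayesian stable-isotope mixing models for reconstructing diet from bone
and sequential dentine collagen.

## The problem

Bulk collagen δ¹³C and δ¹⁵N record the protein component of diet: δ¹³C
separates marine from terrestrial (and C₃ from C₄) food webs, δ¹⁵N rises
about 3‰ per trophic level. A mixing model inverts consumer values into
the proportions in which candidate food-source groups (e.g. marine fish,
freshwater fish, terrestrial animals, C₃ plants) were consumed.

Classic mixing models assume one independent measurement per consumer.
Sequential dentine sampling breaks that assumption: a tooth is cut into
ordered slices, each recording diet during a window of childhood, so one
individual contributes many correlated measurements. `isodiet` fits bone
consumers (one measurement each) and dentine consumers (J slices each) in
a single joint model by adding hierarchical error terms at the individual
and the sample level.

## The model

For subgroup g (an age category, or burial-group × age category) with
consumption proportions **p**_g on the simplex, the expected consumer
value for tracer t is the concentration-weighted average of the
TEF-adjusted source means:

    m_{g,t} = Σ_k p_{g,k} c_{k,e(t)} (μ_{k,t} + λ_{k,t}) / Σ_k p_{g,k} c_{k,e(t)}

where c_{k,e} is the elemental concentration (C for δ¹³C, N for δ¹⁵N) of
source k, μ_{k,t} its tracer mean (estimated, informed by reference
samples with SD τ_{k,t}), and λ_{k,t} the trophic enrichment factor
(defaults +1‰ δ¹³C, +3‰ δ¹⁵N).

A bone measurement is `m + a_i` with individual effect
`a_i ~ N(0, σ_ind²)`; a dentine slice is `m + a_i + e_ij` with slice noise
`e_ij ~ N(0, σ_samp²)`. Marginally a tooth's slices follow a multivariate
normal with compound-symmetry covariance `σ_ind²·11ᵀ + σ_samp²·I`.
Proportions carry a flat Dirichlet(1,…,1) prior per subgroup (marginally
Beta(1, K−1) per component); all other parameters get weakly informative
priors. Sampling is by ensemble MCMC over an unconstrained
parameterization; posteriors are reported as quartiles, KDE modes and
50%/95% HPD intervals, with boundary-reflected kernel density estimates
on [0, 1].

## Worked example

```python
import isodiet as iso

truth = iso.default_truth(seed=1)           # 4 sources, 3 age categories
dataset = iso.generate_dataset(truth)       # bone + dentine consumers

model = iso.DietMixingModel(chains=2, warmup=1200, draws=500, seed=1)
model.fit(dataset)
print(model.predict().round(3))             # posterior-median proportions
```

which prints (rows: subgroups, columns: sources; truth for the adult row
was 0.45 / 0.05 / 0.35 / 0.15):

```
            marine_fish  freshwater_fish  terrestrial_animals  c3_plants
5-9 years         0.268            0.311                0.155      0.239
9-15 years        0.420            0.256                0.076      0.230
adults            0.406            0.223                0.198      0.156
```

Medians track the truth to within roughly the posterior spread at this
sample size; the two isotopically overlapping sources (freshwater fish
and terrestrial animals) trade mass against each other, which is the
expected behavior when tracers cannot separate them. `model.summary_`
holds the full reporting table (quartiles, modes, HPD intervals) and
`model.diagnostics_` the split-R̂/ESS table.

The same workflow is available from the shell:

```
isodiet simulate -o data --seed 3
isodiet fit -c config.yaml        # writes draws, diagnostics, summaries
isodiet recover -n 5 --seed 2     # synthetic recovery experiment
```

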