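# ersmix — mixture random-effect IRT models for extreme response style

Respondents do not all use a rating scale the same way: some gravitate to
the endpoints regardless of content (extreme response style, ERS), others to
the middle categories (mild response style, MRS). Left unmodeled, these
styles bias latent-trait estimates, masquerade as differential item
functioning across unobserved subgroups, and reshuffle respondent rankings.

`ersmix` is a Python library (with a thin CLI) for psychometricians and
survey methodologists that jointly *quantifies* each respondent's style
tendency and *classifies* respondents into normal / ERS / MRS latent
classes, while allowing class-specific item difficulties (latent DIF) and
scoring each item's propensity to elicit styled responding.

## The models

All models are adjacent-category logit models built on the generalized
partial credit model (GPCM). For categories *j = 0..J−1*:

- **GPCM**: log [P(j)/P(j−1)] = α_i θ_n − (β_i + τ_ij)
- **ERS-GPCM**: log [P(j)/P(j−1)] = α_i θ_n − (β_i + ω_n τ_ij), with a
  person weight ω_n > 0 on the thresholds. ω < 1 contracts the scale (more
  extremes), ω > 1 expands it (more middle responses), ω ≡ 1 is the GPCM.
- **Mixture ERS-GPCM**: latent classes g with class-specific difficulties
  β_ig, class-specific θ and ω distributions, and ordered mixing
  proportions. The normal class is pinned at θ ~ N(0,1), ω ≡ 1.
- **Mixture ERS-GPCM-CD**: item-specific style discriminations constrained
  by a fixed total discrimination, α_i1² + α_i2² = MDP², acting through the
  effective threshold weight η_ni = ω_n^{α_i2}. Items with small α_i2 are
  nearly immune to response style — α_i2 is the item-quality score.
- Multidimensional variants (one trait per subscale, a common ω) and the
  GRSM / PCM / RSM restrictions.

Estimation is Bayesian MCMC (a vectorized Metropolis-within-Gibbs sampler
written for this model family) with Brooks–Gelman multivariate PSRF
convergence checks, EAP summaries, Rao–Blackwellized class memberships, and
BIC model comparison via Gauss–Hermite-integrated observed-data likelihoods.
See `docs/methods.md` for the full account.

## Worked example

`examples/02_simulate_and_fit.py` simulates 800 respondents × 20 four-point
items under the three-class mixture (50% normal, 25% ERS with
ω ~ lognormal(−1, 0.4²), 25% MRS with ω ~ lognormal(1, 0.4²)), fits the
mixture ERS-GPCM with a short chain, and prints:

```
simulated 800 x 20 responses, true class sizes [400 195 205]
correct classification rate: 0.779 (normal 0.900, ERS 0.544, MRS 0.766)
RMSE(theta) = 0.326, RMSE(omega) = 0.575
class omega log-means: [ 0.   -1.41  1.13] (generating: 0, -1, +1)
mixing proportions:    [0.58 0.17 0.26] (generating: 0.50, 0.25, 0.25)
```

Reading the numbers: 78% of respondents are assigned to their generating
style class; the target trait is recovered more precisely than the style
weight (RMSE 0.33 vs 0.58), and the fitted class-level ω distributions
separate the ERS (log-mean < 0) and MRS (log-mean > 0) classes without
label switching. The other examples show how ω reshapes category
probabilities (`01`), what ignoring the mixture costs — classification
accuracy collapses and misclassified respondents' traits shrink toward zero
(`03`) — and BIC model comparison plus item-level ERS diagnostics (`04`).

The CLI mirrors the library:

```bash
ersmix simulate --config design.yaml --out sim/
ersmix fit --responses sim/responses.csv --model mix-ers-gpcm --classes 3 --out fit/
ersmix evaluate --posterior fit/posterior.json --truth sim/truth.json --out eval/
ersmix replicate --config study.yaml --reps 30 --out study/
```

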