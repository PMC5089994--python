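# Methods

## The measurement problem

Self-report instruments score ordered rating categories (Likert scales) as
if every respondent used the scale the same way. In practice some
respondents systematically prefer the endpoint categories (extreme response
style, ERS) and others the middle categories (mild response style, MRS),
independently of the trait being measured. Ignoring these styles biases
trait estimates, inflates or deflates item difficulties differently across
unobserved subgroups (latent differential item functioning), and distorts
rank orderings of respondents. `ersmix` implements a family of mixture
random-effect item response models that simultaneously (a) quantify each
respondent's style tendency on a continuum, (b) classify respondents into
normal / ERS / MRS latent classes with class-specific item difficulties, and
(c) score each item's propensity to elicit styled responding.

## Model family

All members are adjacent-category logit models. With categories
`j = 0..J-1`, discrimination `alpha_i`, overall difficulty `beta_i` and step
thresholds `tau_ij` (`J-1` per item), the generalized partial credit model
(GPCM) sets

    log P(j) / P(j-1) = alpha_i * theta_n - (beta_i + tau_ij).

The family then adds, cumulatively:

- **ERS-GPCM** — a person-level positive weight `omega_n` multiplying the
  thresholds: `... - (beta_i + omega_n * tau_ij)`. `omega < 1` contracts the
  scale (more endpoint responses), `omega > 1` expands it (more middle
  responses); `omega = 1` recovers the GPCM exactly. `omega` is lognormal
  with log-mean zero in the single-class model.
- **Mixture ERS-GPCM** — latent classes `g` (class 0 = normal) with
  class-specific difficulties `beta_ig` (latent DIF), class-specific normal
  `theta` distributions and lognormal `omega` distributions. Identification:
  the normal class has `theta ~ N(0,1)` and `omega = 1`; item difficulties
  average zero within every class; the normal class keeps the largest mixing
  proportion (ordinal constraint on the mixing vector).
- **Mixture ERS-GPCM-CD** — a free item discrimination on the style
  dimension would not be identified jointly with `omega` and `tau`
  (three multiplied parameter types). The constrained-discrimination (CD)
  variant ties the two discriminations through a fixed total
  `alpha_i1^2 + alpha_i2^2 = MDP^2` (one MDP per subscale) and damps the
  style effect item by item through the effective weight
  `eta_ni = exp(alpha_i2 * log omega_n) = omega_n ** alpha_i2`.
  `alpha_i2 -> 0` makes an item immune to response style, which is how the
  model scores item quality.
- **Multidimensional variants** — each item loads on exactly one subscale
  trait `theta_ns`; the style weight is common across subscales
  (response styles are assumed content-independent).
- **Restrictions** — GRSM (one threshold vector shared by all items),
  PCM (`alpha_i1 = 1`), RSM (both).

One documented non-model: the fully general form with free style
discriminations and no MDP constraint is not identifiable and is therefore
not estimable here.

A note on the latent trait: the trait is normal in every class
(`N(mu_theta_g, sigma2_theta_g)`, standard normal in the normal class).
Only `omega` is lognormal.

## Synthetic data

The simulator's defaults are the generating conditions of the recovery
studies this package reproduces, and they double as a realistic picture of
survey data in which about half the sample responds "normally":

| quantity | default |
|---|---|
| class proportions (normal/ERS/MRS) | 0.50 / 0.25 / 0.25 |
| theta (every class) | N(0, 1) |
| omega: normal / ERS / MRS | 1 / lognormal(-1, 0.4^2) / lognormal(1, 0.4^2) |
| discriminations alpha_1 | lognormal(meanlog 0, sdlog 0.2) |
| normal-class difficulties | uniform(-1.5, 1.5), centered to mean 0 |
| style-class difficulty shift | +-0.5, balanced so class means stay equal |
| thresholds, 4-point / 6-point | (-0.6, 0, 0.6) / (-0.8, -0.4, 0, 0.4, 0.8) |
| total discrimination MDP (CD) | 1.50 |

Two generator choices were genuinely open and are fixed as follows. The
+-0.5 difficulty shift is assigned to a random half of the items with
positive sign and the other half negative (an odd leftover item gets a
random sign and the shift vector is re-centered), so that mean difficulty is
exactly equal across classes. The discrimination distribution uses meanlog 0
because that is the parameterization consistent with draws in the 0.62–1.45
range and with the MDP = 1.5 feasibility bound `alpha_1 <= MDP`; a meanlog-1
parameterization can be requested in the design. For CD designs, `alpha_1`
draws above the MDP are redrawn.

What the generator does *not* emulate: correlated trait and style
(independence is assumed), missing responses, within-person drift of style
over items or time, and more than one "abnormal" style pair. Passing
recovery tests therefore show that the estimator inverts its own generating
model at realistic survey sizes — not that real questionnaire data contain
exactly three classes.

## Estimation

The models are estimated by MCMC with the following priors: N(0, 4) for all
difficulties and thresholds, lognormal(0, 1) for discriminations and the
MDP, N(0, 10) for style-class trait means, Gamma(0.01, 0.01) for latent
precisions, N(-0.5, 10) / N(+0.5, 10) for the log-mean of `omega` in the ERS
and MRS classes (the opposite-sign centers are the label-switching guard,
together with the dominant-normal-class ordering of the mixing proportions),
and a symmetric Dirichlet(1) over the ordered mixing vector.

The sampler is a vectorized Metropolis-within-Gibbs scheme:

- **Class indicators**: exact categorical full conditionals, all respondents
  in parallel. While a respondent occupies the normal class their personal
  style weight has no likelihood role; it is kept well defined by a
  Carlin–Chib pseudo-prior — a fixed two-component normal mixture on
  `log omega` centered at the +-0.5 prior centers (sd 0.6). The mixture form
  matters: it keeps proposing style-like weights for respondents parked in
  the normal class, so normal-to-style transitions actually occur. Class
  assignments are frozen for the first 25 burn-in iterations so person and
  item parameters can adapt before the classes compete.
- **Person parameters**: random-walk Metropolis for `theta` (per subscale)
  and `log omega`, independent across respondents given the rest, executed
  as single vectorized accept/reject passes.
- **Item parameters**: log-scale random walks per item for `alpha_1` and the
  MDP (proposals violating `alpha_1 <= MDP` are rejected). Difficulties and
  thresholds live on sum-to-zero manifolds and move by paired increments —
  one randomly chosen item (or threshold) up, its partner down — so the
  identification constraints hold *exactly in every draw*, not just on
  average. Disjoint pairs are conditionally independent because the
  likelihood factorizes over items, so all pairs update in one vectorized
  pass.
- **Class distributions**: conjugate normal/gamma updates for the latent
  means and variances; Dirichlet update with rejection for the ordered
  mixing proportions. Latent variances are truncated to [1e-4, 4]: with the
  vague gamma prior, an accidentally emptied class would otherwise draw an
  enormous variance, assign essentially zero density to every respondent and
  never recover. The cap is far above any plausible posterior value and only
  binds in that degenerate state.

Proposal step sizes adapt toward 0.44 acceptance during burn-in only, so the
retained draws come from a fixed kernel. Defaults follow the reference
recipe: 15,000 iterations, 5,000 burn-in, 3 chains. Convergence is assessed
with the Brooks–Gelman multivariate potential scale reduction factor,
computed per parameter block and overall on the free (constraint-reduced)
coordinates; "close to unity" is operationalized as <= 1.10, and
non-convergence raises a warning (and a non-zero exit from the CLI), never a
silent pass. Label stability is assertable directly on the draws: the class
whose `omega` log-mean is negative is ERS in every retained draw.

Person summaries are marginal posterior means (EAP): `theta` and effective
`omega` (equal to 1 whenever the respondent sits in the normal class) are
accumulated over retained draws, class-membership probabilities are
Rao–Blackwellized averages of the per-draw conditional class probabilities.
Modal assignment breaks exact ties toward the normal class. EAP estimation
shrinks trait estimates toward the prior mean, which is visible as an
estimate-on-truth regression slope below 1.

### Marginal likelihood and BIC

Model comparison uses `BIC = -2 logL + k log N` at the EAP parameter values,
where `logL` is the observed-data likelihood with class membership summed
out and the person effects integrated by Gauss–Hermite quadrature (15 nodes
per dimension, centered at each class's latent distribution; the `omega`
dimension is dropped where it is degenerate). Because items partition across
subscales and the trait components are independent given `omega`, the
multidimensional integral factorizes into per-subscale one-dimensional
quadratures inside the `omega` quadrature. `k` counts free structural
parameters only: sum-to-zero constraints remove one difficulty per class and
one threshold per item, the style discriminations of a CD model are not
counted (the MDP is), and person effects are integrated, not counted.

### The naive style classifier

For the misfit analyses, the single-class ERS-GPCM yields a Wald-type
classifier: `(omega_hat - 1) / SE` with SE the posterior standard deviation
of `omega` (the reference analysis leaves the SE definition open; posterior
SD is the natural Bayesian choice). Below -1.96 is called ERS, above +1.96
MRS, otherwise normal. The test is conservative with short tests — most
styled respondents land in the normal class, which is exactly the failure
mode the mixture model repairs.

## Design choices on open points

- EAP person summaries are marginal over classes by default; conditioning on
  the modal class is available by combining `classify` with stored person
  draws.
- Thresholds are class-invariant (only difficulties carry latent DIF), and
  discriminations are class-invariant by default with an optional
  class-specific relaxation for metric-invariance checks (not available for
  CD models, where discriminations are tied to the MDP).
- Rank-order-change diagnostics rank estimates with ties broken by
  respondent position, so the statistic is deterministic.
- Per-class classification rates use true-class denominators; both the
  pooled (size-weighted) and macro-averaged summaries are reported, the
  pooled one being the headline figure.
- Multidimensional estimation treats the trait components as independent
  standard normals in the normal class; subscale covariances are not
  estimated (a known limitation — the probability kernels and the simulator
  support correlated traits, the sampler does not).

## Problem sizes used by the test suite

The reference recovery studies use 30 replications of 15,000-iteration
3-chain runs per condition; the shipped test suite reproduces their
qualitative structure at package-test scale: 1,400 iterations (500 burn-in),
one or two chains, two replications of the N=1000 / 20-item / 4-point
condition (plus one each of the 40-item and 6-point variants), with the
N=500 condition fit on a respondent subsample of the matched N=1000
replicate so the sample-size comparison is paired. At this scale the
asserted results are directional (trait recovered better than style weight;
six categories beat four; long tests beat short; mixture classification
beats the naive Wald classifier by more than 0.1; accuracy degrades at
N=500) rather than table-value reproductions. Observed values at this scale
sit close to the reference ones (e.g. overall classification accuracy ~0.74
and trait RMSE ~0.29 in the base condition).

## Known limitations

- A random-walk Gibbs sampler needs long chains for strict PSRF <= 1.10 at
  full survey sizes; the defaults match the reference recipe, but short
  demonstration chains will (correctly) warn about non-convergence.
- Mixture fits below roughly 1,000 respondents or 20 items are unreliable
  (the fit warns); classes can be weakly separated and the `omega` variance
  of a small class is poorly determined.
- No multilevel, longitudinal, or item-covariate (LLTM-style) extensions; no
  correlated trait-style persons; no missing-data handling.
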