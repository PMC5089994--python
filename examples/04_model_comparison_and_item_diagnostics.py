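"""BIC model comparison and item-level ERS diagnostics.

Compares single-class and mixture fits by BIC on mixture-generated CD data,
then ranks items by their propensity to elicit extreme responding (alpha2,
the discrimination on the omega dimension, recovered from the MDP split
alpha1^2 + alpha2^2 = MDP^2) and reports class-specific difficulty gaps as a
latent-DIF screen.
"""

import warnings

import numpy as np

from ersmix import (
    McmcConfig,
    ModelSpec,
    SimulationDesign,
    bic,
    eap_item_parameters,
    fit,
    item_ers_elicitation,
    rank_order_change,
    simulate_dataset,
)

design = SimulationDesign(n_respondents=1200, n_items=24, n_categories=4, mdp=1.5, seed=29)
data = simulate_dataset(design)
mcmc = McmcConfig(n_iterations=1200, n_burnin=500, n_chains=1, seed=29)

fits = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for name, spec in {
        "ers-gpcm (1 class)": ModelSpec(family="ers-gpcm", n_categories=4),
        "mix-ers-gpcm-cd (3 classes)": ModelSpec(
            family="mix-ers-gpcm-cd", n_classes=3, n_categories=4
        ),
    }.items():
        fits[name] = fit(data, spec, mcmc=mcmc)
        print(f"BIC {name:<28}: {bic(fits[name], data):,.0f}")
print("-> smaller BIC wins; with enough respondents the generating"
      " three-class CD model overcomes its larger parameter count")

best = fits["mix-ers-gpcm-cd (3 classes)"]
items = eap_item_parameters(best)
diag = item_ers_elicitation(items)
order = diag["ranking"]
print("\nitems most likely to elicit ERS/MRS (highest alpha2):",
      [int(i) + 1 for i in order[:3]])
print("items most robust to response style (lowest alpha2):",
      [int(i) + 1 for i in order[-3:]])
print("largest normal-vs-ERS difficulty gap (latent DIF screen): "
      f"item {int(np.argmax(diag['beta_diff_class_1'])) + 1} "
      f"({diag['beta_diff_class_1'].max():.2f})")

reduced = fits["ers-gpcm (1 class)"]
roc = rank_order_change(best.theta_eap, reduced.theta_eap)
print(f"\nrank-order changes in theta when mixtures are ignored: "
      f"max {roc['max']}, mean {roc['mean']:.1f} of {data.n_respondents} respondents")
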