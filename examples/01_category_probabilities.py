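"""How the style weight omega reshapes rating-scale category probabilities.

A respondent with omega < 1 contracts the distance between step thresholds
(extreme categories become more likely, ERS); omega > 1 expands it (middle
categories, MRS).  The constrained-discrimination (CD) model damps the style
effect item by item through eta = omega ** alpha2.
"""

import numpy as np

from ersmix import ers_gpcm_probs, eta_weight, gpcm_category_probs

tau = np.array([-0.6, 0.0, 0.6])  # 4-point item, centered thresholds

print("4-point item, alpha=1, beta=0, theta=0")
print(f"  plain GPCM              : {np.round(gpcm_category_probs(0, 1, 0, tau), 3)}")
for omega, label in [(0.5, "ERS (omega=0.5)"), (1.5, "MRS (omega=1.5)")]:
    p = ers_gpcm_probs(0, 1, 0, tau, omega)
    print(f"  {label:<24}: {np.round(p, 3)}")
print("  -> the ERS row piles mass on categories 1 and 4, the MRS row on 2 and 3")

print("\nCD model: effective threshold weight eta = omega ** alpha2 (alpha2 = 0.2)")
for omega in (0.5, 1.0, 1.5):
    print(f"  omega = {omega:3.1f} -> eta = {eta_weight(omega, 0.2):.2f}")
print("  -> a small alpha2 pulls eta toward 1: a well-written item nearly "
      "neutralizes the response style")
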