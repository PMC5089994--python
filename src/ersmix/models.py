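"""Category-probability functions for the ERS mixture IRT model family.

The family is built on the generalized partial credit model (GPCM), an
adjacent-category logit model for ordered responses.  A person-level weight
``omega`` multiplies the step thresholds: ``omega < 1`` contracts the scale
(extreme categories become more attractive, the extreme response style, ERS),
``omega > 1`` expands it (middle categories, MRS).  Latent classes (normal /
ERS / MRS) carry class-specific overall item difficulties so that latent DIF
can be expressed.  The constrained-discrimination (CD) variant replaces the
raw weight by an item-modulated weight ``eta = omega ** alpha2``, where the
per-item discrimination on the style dimension ``alpha2`` is tied to the
discrimination on the target trait through a fixed total discrimination
``alpha1**2 + alpha2**2 == MDP**2``.

Categories are indexed ``0 .. J-1`` internally; there are ``J-1`` step
thresholds per item and the adjacent log-odds of category ``j`` over ``j-1``
is ``alpha * theta - (beta + w * tau_j)`` with ``w`` equal to 1 (GPCM),
``omega`` (ERS models) or ``eta`` (CD models).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ItemParameters",
    "ClassSpec",
    "PersonState",
    "gpcm_category_probs",
    "ers_gpcm_probs",
    "mixture_ers_gpcm_probs",
    "cd_model_probs",
    "multidim_cd_probs",
    "eta_weight",
    "alpha2_from_mdp",
    "restrict_model",
    "adjacent_logits_to_probs",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ItemParameters:
    """Item-side parameters for a test of I items with J ordered categories.

    Attributes
    ----------
    alpha1 : (I,) positive discriminations on the target trait.
    beta : (G, I) class-specific overall difficulties; within each class the
        item mean is zero when the identification constraint is active.
    tau : (I, J-1) step thresholds (shared across classes).
    alpha2 : (I,) optional discriminations on the style dimension (CD models).
    mdp : optional total discrimination per subscale (scalar or (S,));
        when set, ``alpha2 = sqrt(mdp**2 - alpha1**2)`` item by item.
    subscale_of_item : (I,) integer subscale index per item (all zero for
        unidimensional tests).
    """

    alpha1: np.ndarray
    beta: np.ndarray
    tau: np.ndarray
    alpha2: Optional[np.ndarray] = None
    mdp: Optional[np.ndarray] = None
    subscale_of_item: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.alpha1 = np.atleast_1d(np.asarray(self.alpha1, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        if self.alpha2 is not None:
            self.alpha2 = np.atleast_1d(np.asarray(self.alpha2, dtype=float))
        if self.mdp is not None:
            self.mdp = np.atleast_1d(np.asarray(self.mdp, dtype=float))
        if self.subscale_of_item is None:
            self.subscale_of_item = np.zeros(self.n_items, dtype=int)
        else:
            self.subscale_of_item = np.asarray(self.subscale_of_item, dtype=int)
        self.validate()

    @property
    def n_items(self) -> int:
        return self.alpha1.shape[0]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_categories(self) -> int:
        return self.tau.shape[1] + 1

    @property
    def n_subscales(self) -> int:
        return int(self.subscale_of_item.max()) + 1

    def validate(self) -> None:
        if self.tau.shape[1] < 1:
            raise ValueError("tau must have at least one threshold (J >= 2)")
        if np.any(self.alpha1 <= 0):
            raise ValueError("alpha1 must be strictly positive")
        if self.beta.shape[1] != self.n_items or self.tau.shape[0] != self.n_items:
            raise ValueError("beta/tau item dimension mismatch with alpha1")
        if self.alpha2 is not None:
            if self.alpha2.shape[0] != self.n_items:
                raise ValueError("alpha2 length must equal the number of items")
            if np.any(self.alpha2 < 0):
                raise ValueError("alpha2 must be non-negative")
        if self.mdp is not None and np.any(self.mdp <= 0):
            raise ValueError("mdp must be strictly positive")

    def effective_alpha2(self) -> np.ndarray:
        """alpha2 per item, derived from MDP when not stored directly."""
        if self.alpha2 is not None:
            return self.alpha2
        if self.mdp is None:
            raise ValueError("neither alpha2 nor mdp available")
        mdp_item = self.mdp[self.subscale_of_item] if self.mdp.shape[0] > 1 else self.mdp[0]
        return alpha2_from_mdp(mdp_item, self.alpha1)


@dataclass
class ClassSpec:
    """Latent-class mixing proportions and latent-distribution parameters.

    Class 0 is the normal class: theta ~ N(0, 1) and omega fixed at 1.  Style
    classes carry free normal parameters for theta and for log(omega).  The
    ordinal identification constraint requires the normal class to have the
    largest mixing proportion.
    """

    mixing: np.ndarray
    theta_mean: np.ndarray
    theta_var: np.ndarray
    omega_logmean: np.ndarray
    omega_logvar: np.ndarray
    theta_cov: Optional[np.ndarray] = None  # (S, S), multidimensional model

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.theta_mean = np.asarray(self.theta_mean, dtype=float)
        self.theta_var = np.asarray(self.theta_var, dtype=float)
        self.omega_logmean = np.asarray(self.omega_logmean, dtype=float)
        self.omega_logvar = np.asarray(self.omega_logvar, dtype=float)
        self.validate()

    @property
    def n_classes(self) -> int:
        return self.mixing.shape[0]

    def validate(self) -> None:
        if not np.isclose(self.mixing.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.mixing < 0):
            raise ValueError("mixing proportions must be non-negative")
        if np.any(self.mixing[0] + 1e-12 < self.mixing[1:]):
            raise ValueError("normal class must have the largest mixing proportion")
        tm = np.atleast_1d(self.theta_mean[0])
        tv = np.atleast_1d(self.theta_var[0])
        if not (np.allclose(tm, 0.0) and np.allclose(tv, 1.0)):
            raise ValueError("normal class requires theta ~ N(0, 1)")
        if not np.isclose(self.omega_logmean[0], 0.0):
            raise ValueError("class 0 requires a unit median omega (log-mean 0)")
        if self.n_classes > 1 and not np.isclose(self.omega_logvar[0], 0.0):
            # in a mixture the normal class pins omega at exactly 1; a single
            # class may keep a free omega variance (the plain ERS model)
            raise ValueError("normal class requires omega fixed at 1")
        if np.any(self.omega_logvar < 0) or np.any(np.atleast_1d(self.theta_var) <= 0):
            raise ValueError("variances must be positive")


@dataclass
class PersonState:
    """One respondent's latent state.

    ``theta`` is a scalar (or length-S vector for multidimensional tests),
    ``omega`` the positive threshold weight, ``class_label`` the latent class
    index (0 = normal).
    """

    theta: np.ndarray
    omega: float
    class_label: int = 0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.omega <= 0:
            raise ValueError("omega must be strictly positive")
        if self.class_label < 0:
            raise ValueError("class_label must be a valid class index")

    def eta(self, alpha2: np.ndarray) -> np.ndarray:
        """Per-item effective threshold weights eta = omega ** alpha2."""
        return eta_weight(self.omega, np.asarray(alpha2, dtype=float))


# ---------------------------------------------------------------------------
# probability kernels


def adjacent_logits_to_probs(z: np.ndarray) -> np.ndarray:
    """Map adjacent-category log-odds (..., J-1) to category probabilities (..., J).

    Cumulative sums of the adjacent log-odds give unnormalized category
    log-weights (zero for the baseline category); a log-sum-exp normalization
    keeps the computation stable for extreme logits.
    """
    z = np.asarray(z, dtype=float)
    cum = np.cumsum(z, axis=-1)
    zeros = np.zeros(cum.shape[:-1] + (1,))
    cum = np.concatenate([zeros, cum], axis=-1)
    cum -= cum.max(axis=-1, keepdims=True)
    w = np.exp(cum)
    return w / w.sum(axis=-1, keepdims=True)


def gpcm_category_probs(theta: float, alpha: float, beta: float, tau: np.ndarray) -> np.ndarray:
    """GPCM category probabilities for one person on one item.

    The adjacent log-odds of category ``j`` over ``j-1`` is
    ``alpha * theta - (beta + tau[j])``.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise ValueError("tau must contain at least one threshold")
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    z = alpha * theta - (beta + tau)
    return adjacent_logits_to_probs(z)


def ers_gpcm_probs(
    theta: float, alpha: float, beta: float, tau: np.ndarray, omega: float
) -> np.ndarray:
    """ERS-GPCM probabilities: the person weight ``omega`` scales the thresholds.

    ``omega == 1`` reproduces the plain GPCM bit for bit.
    """
    if omega <= 0:
        raise ValueError("omega must be strictly positive")
    tau = np.asarray(tau, dtype=float)
    return gpcm_category_probs(theta, alpha, beta, omega * tau)


def mixture_ers_gpcm_probs(
    person: PersonState, item_params: ItemParameters, class_index: int
) -> np.ndarray:
    """Mixture ERS-GPCM probabilities, (I, J), using class-specific difficulties.

    The normal class (index 0) uses omega = 1 regardless of the stored person
    weight; style classes use the person's omega.
    """
    omega = _class_omega(person, item_params, class_index)
    beta_g = item_params.beta[class_index]
    theta = _item_theta(person, item_params)
    z = item_params.alpha1[:, None] * theta[:, None] - (
        beta_g[:, None] + omega * item_params.tau
    )
    return adjacent_logits_to_probs(z)


def _class_omega(person: PersonState, item_params: ItemParameters, class_index: int) -> float:
    """omega entering the kernel: pinned at 1 for the normal class of a mixture."""
    if not 0 <= class_index < item_params.n_classes:
        raise ValueError(f"no class-specific difficulties for class {class_index}")
    omega = 1.0 if (class_index == 0 and item_params.n_classes > 1) else person.omega
    if omega <= 0:
        raise ValueError("omega must be strictly positive")
    return omega


def cd_model_probs(
    person: PersonState, item_params: ItemParameters, class_index: int
) -> np.ndarray:
    """Mixture ERS-GPCM-CD probabilities, (I, J).

    The thresholds are scaled by the item-modulated weight
    ``eta_i = omega ** alpha2_i`` instead of the raw omega; with
    ``alpha2 == 1`` everywhere this is the plain mixture ERS-GPCM.
    """
    omega = _class_omega(person, item_params, class_index)
    alpha2 = item_params.effective_alpha2()
    eta = eta_weight(omega, alpha2)
    beta_g = item_params.beta[class_index]
    theta = _item_theta(person, item_params)
    z = item_params.alpha1[:, None] * theta[:, None] - (
        beta_g[:, None] + eta[:, None] * item_params.tau
    )
    return adjacent_logits_to_probs(z)


def multidim_cd_probs(
    person: PersonState,
    item_params: ItemParameters,
    class_index: int,
    subscale: Optional[int] = None,
) -> np.ndarray:
    """Multidimensional CD-model probabilities.

    Each item loads on exactly one subscale's theta component; the style
    weight omega is common to all subscales, so the per-item eta does not
    depend on the subscale.  With a single subscale this is bit-identical to
    :func:`cd_model_probs`.  When ``subscale`` is given, only that subscale's
    items are returned.
    """
    probs = cd_model_probs(person, item_params, class_index)
    if subscale is None:
        return probs
    mask = item_params.subscale_of_item == subscale
    if not mask.any():
        raise ValueError(f"no items on subscale {subscale}")
    return probs[mask]


def _item_theta(person: PersonState, item_params: ItemParameters) -> np.ndarray:
    """Per-item theta: the component of the person's trait each item loads on."""
    sub = item_params.subscale_of_item
    if int(sub.max()) >= person.theta.shape[0]:
        raise ValueError("item refers to a subscale the person has no theta for")
    return person.theta[sub]


# ---------------------------------------------------------------------------
# CD re-parameterization helpers


def eta_weight(omega, alpha2):
    """Effective threshold weight eta = exp(alpha2 * log(omega)) = omega**alpha2.

    A small alpha2 pulls eta toward 1, damping the style effect on that item;
    alpha2 = 0 removes it entirely.
    """
    omega = np.asarray(omega, dtype=float)
    alpha2 = np.asarray(alpha2, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    if np.any(alpha2 < 0):
        raise ValueError("alpha2 must be non-negative")
    out = np.power(omega, alpha2)  # == exp(alpha2 * log(omega)); pow is exact at 0 and 1
    return out if out.ndim else float(out)


def alpha2_from_mdp(mdp, alpha1):
    """Split a fixed total discrimination: alpha2 = sqrt(mdp**2 - alpha1**2)."""
    mdp = np.asarray(mdp, dtype=float)
    alpha1 = np.asarray(alpha1, dtype=float)
    if np.any(alpha1 > mdp + 1e-12):
        raise ValueError("alpha1 may not exceed the total discrimination mdp")
    out = np.sqrt(np.maximum(mdp**2 - alpha1**2, 0.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# restrictions


_RESTRICTIONS = ("GRSM", "PCM", "RSM")


def restrict_model(item_params: ItemParameters, restriction: str) -> ItemParameters:
    """Apply a named restriction to an item bank.

    GRSM ties the threshold vector across items (item means of tau), PCM fixes
    all target-trait discriminations at 1, RSM applies both.  Restrictions are
    idempotent and RSM == PCM o GRSM in either order.
    """
    if restriction not in _RESTRICTIONS:
        raise ValueError(f"unknown restriction {restriction!r}; expected one of {_RESTRICTIONS}")
    out = replace(item_params)
    if restriction in ("GRSM", "RSM"):
        shared = out.tau.mean(axis=0)
        out = replace(out, tau=np.tile(shared, (out.n_items, 1)))
    if restriction in ("PCM", "RSM"):
        out = replace(out, alpha1=np.ones(out.n_items))
        # alpha2 derived from an MDP would change with alpha1; keep stored alpha2.
    return out
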