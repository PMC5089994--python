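"""Bayesian MCMC estimation for the ERS mixture IRT model family.

The sampler is a Metropolis-within-Gibbs scheme with explicit latent-class
indicators:

* class indicators are drawn from their exact categorical full conditional
  (a Carlin–Chib pseudo-prior keeps the per-person style weight well defined
  while a person sits in the normal class, whose weight is fixed at 1);
* person traits and log style weights use vectorized random-walk Metropolis
  updates (independent across persons given everything else);
* item discriminations use per-item random-walk updates on the log scale;
* class-specific overall difficulties and step thresholds live on sum-to-zero
  manifolds and move by paired increment proposals (one item up, one down),
  which preserves the identification constraint in every single draw;
* latent-distribution means and variances use conjugate normal/gamma Gibbs
  updates, and the mixing proportions a Dirichlet update with rejection to
  enforce the dominant-normal-class ordering.

Identification follows the usual mixture-IRT conventions: the normal class
has theta ~ N(0, 1) and omega = 1, item difficulties average zero within each
class, thresholds sum to zero per item, and the normal class keeps the
largest mixing proportion.  Label switching between the ERS and MRS classes
is prevented by prior centers of -0.5 and +0.5 on the lognormal mean of
omega.

Proposal step sizes adapt toward a 0.44 acceptance rate during burn-in only,
so the retained draws come from a fixed (valid) kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp

from .models import ClassSpec, ItemParameters
from .simulate import ResponseMatrix

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "McmcConfig",
    "PosteriorSummary",
    "fit",
    "psrf",
    "psrf_univariate",
    "classify",
    "naive_ers_classify",
    "bic",
    "marginal_loglik",
    "eap_item_parameters",
    "eap_class_spec",
    "CLASS_NAMES",
]

CLASS_NAMES = ("normal", "ERS", "MRS")

_FAMILIES = ("gpcm", "ers-gpcm", "ers-gpcm-cd", "mix-ers-gpcm", "mix-ers-gpcm-cd")


# ---------------------------------------------------------------------------
# specifications


@dataclass
class ModelSpec:
    """Which member of the model family to fit.

    ``family`` is one of ``gpcm``, ``ers-gpcm``, ``ers-gpcm-cd`` (all single
    class) or ``mix-ers-gpcm`` / ``mix-ers-gpcm-cd`` with ``n_classes >= 2``.
    ``restriction`` optionally ties thresholds across items (GRSM), fixes the
    discriminations at one (PCM), or both (RSM).  ``subscale_of_item`` turns
    on the multidimensional variant (one trait per subscale, a common omega).
    """

    family: str
    n_classes: int = 1
    n_categories: int = 4
    restriction: Optional[str] = None
    subscale_of_item: Optional[np.ndarray] = None
    class_specific_alpha: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.is_mixture and self.n_classes < 2:
            raise ValueError("mixture families require n_classes >= 2")
        if not self.is_mixture and self.n_classes != 1:
            raise ValueError(f"{self.family} is a single-class model")
        if self.restriction is not None and self.restriction not in ("GRSM", "PCM", "RSM"):
            raise ValueError(f"unknown restriction {self.restriction!r}")
        if self.n_categories < 2:
            raise ValueError("need at least two response categories")
        if self.subscale_of_item is not None:
            self.subscale_of_item = np.asarray(self.subscale_of_item, dtype=int)
        if self.class_specific_alpha and self.is_cd:
            raise ValueError("class-specific discriminations unsupported for CD models")

    @property
    def is_mixture(self) -> bool:
        return self.family.startswith("mix-")

    @property
    def is_cd(self) -> bool:
        return self.family.endswith("-cd")

    @property
    def omega_free(self) -> bool:
        return self.family != "gpcm"

    @property
    def alpha_free(self) -> bool:
        return self.restriction not in ("PCM", "RSM")

    @property
    def shared_tau(self) -> bool:
        return self.restriction in ("GRSM", "RSM")

    def n_subscales(self, n_items: int) -> int:
        if self.subscale_of_item is None:
            return 1
        return int(self.subscale_of_item.max()) + 1

    def n_free_parameters(self, n_items: int) -> int:
        """Count of free structural parameters (identification constraints removed)."""
        I, J, G = n_items, self.n_categories, self.n_classes
        S = self.n_subscales(n_items)
        k = 0
        if self.alpha_free:
            k += I * (G if self.class_specific_alpha else 1)
        if self.is_cd:
            k += S
        k += G * (I - 1)  # sum-to-zero difficulties per class
        if J > 2:
            k += (J - 2) if self.shared_tau else I * (J - 2)
        if G == 1:
            if self.omega_free:
                k += 1  # variance of log omega (mean fixed at zero)
        else:
            k += (G - 1) * (2 * S + 2)  # theta mean/var per subscale, omega logmean/logvar
            k += G - 1  # mixing proportions
        return k


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    Locations and thresholds get N(0, 4); slopes and the MDP get
    lognormal(0, 1); style-class theta means get N(0, 10) and precisions
    Gamma(0.01, 0.01); the lognormal mean of omega gets N(-0.5, 10) for the
    ERS class and N(+0.5, 10) for the MRS class (the opposite-sign centers
    are the label-switching guard); the class indicator is categorical with
    a symmetric Dirichlet(1) on the ordered mixing proportions.
    """

    location_var: float = 4.0
    threshold_var: float = 4.0
    slope_logvar: float = 1.0
    class_theta_mean_var: float = 10.0
    precision_shape: float = 0.01
    precision_rate: float = 0.01
    omega_logmean_centers: Tuple[float, ...] = (-0.5, 0.5)
    omega_logmean_var: float = 10.0
    mixing_concentration: float = 1.0
    # Carlin-Chib pseudo-prior for the style weight while a person sits in the
    # normal class (whose own omega is pinned at 1): a fixed two-component
    # normal mixture on log omega centered at the ERS/MRS prior centers, so
    # that style-like weights keep being proposed and a respondent can leave
    # the normal class again.
    pseudo_omega_logsd: float = 0.6

    def omega_centers(self, n_classes: int) -> np.ndarray:
        centers = np.zeros(n_classes)
        for g in range(1, n_classes):
            centers[g] = self.omega_logmean_centers[(g - 1) % len(self.omega_logmean_centers)]
        return centers


@dataclass
class McmcConfig:
    n_iterations: int = 15000
    n_burnin: int = 5000
    n_chains: int = 3
    seed: int = 0
    thinning: int = 1
    store_person_draws: bool = False
    psrf_threshold: float = 1.10
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorSummary:
    """Posterior summaries of one fit."""

    model_spec: ModelSpec
    mcmc: McmcConfig
    eap: Dict[str, np.ndarray]
    sd: Dict[str, np.ndarray]
    theta_eap: np.ndarray
    theta_sd: np.ndarray
    omega_eap: np.ndarray
    omega_sd: np.ndarray
    membership_probs: np.ndarray
    chains: List[Dict[str, np.ndarray]]
    psrf: Dict[str, float]
    converged: Optional[bool]
    loglik_at_eap: float
    acceptance: Dict[str, float]
    person_draws: Optional[Dict[str, np.ndarray]] = None

    @property
    def n_respondents(self) -> int:
        return self.membership_probs.shape[0]


# ---------------------------------------------------------------------------
# sampler


class _Sampler:
    """One MCMC chain for one response matrix."""

    def __init__(
        self,
        y: np.ndarray,
        spec: ModelSpec,
        priors: PriorSpec,
        rng: np.random.Generator,
        chain_index: int = 0,
    ) -> None:
        self.y = y
        self.spec = spec
        self.priors = priors
        self.rng = rng
        self.N, self.I = y.shape
        self.J = spec.n_categories
        self.G = spec.n_classes
        self.sub = (
            spec.subscale_of_item
            if spec.subscale_of_item is not None
            else np.zeros(self.I, dtype=int)
        )
        self.S = int(self.sub.max()) + 1
        self.cd = spec.is_cd
        # single-class ERS models leave omega free for everyone (log-mean pinned at 0)
        self.single_free_omega = spec.omega_free and self.G == 1
        self._init_state(chain_index)
        self.steps = {"theta": 0.5, "omega": 0.4, "alpha": 0.15, "mdp": 0.05,
                      "beta": 0.15, "tau": 0.1}
        self.accepts: Dict[str, List[float]] = {k: [] for k in self.steps}
        self.class_probs = np.ones((self.N, self.G)) / self.G

    # -- initialization ----------------------------------------------------

    def _init_state(self, chain_index: int) -> None:
        rng, y = self.rng, self.y
        N, I, J, G, S = self.N, self.I, self.J, self.G, self.S
        # person traits: standardized mean scores per subscale
        theta = np.zeros((N, S))
        for s in range(S):
            sc = y[:, self.sub == s].mean(axis=1)
            sd = sc.std()
            theta[:, s] = (sc - sc.mean()) / (sd if sd > 0 else 1.0)
        self.theta = theta + 0.1 * rng.standard_normal((N, S))
        # classes: extreme-response share, jittered per chain
        extreme = ((y == 0) | (y == J - 1)).mean(axis=1)
        extreme = extreme + 0.05 * rng.standard_normal(N)
        labels = np.zeros(N, dtype=int)
        if G >= 2:
            labels[extreme >= np.quantile(extreme, 0.75)] = 1
        if G >= 3:
            labels[extreme <= np.quantile(extreme, 0.25)] = 2
        self.labels = labels
        centers = self.priors.omega_centers(G)
        self.log_omega = centers[labels] + 0.2 * rng.standard_normal(N)
        if self.single_free_omega:
            self.log_omega = 0.2 * rng.standard_normal(N)
        # items
        self.alpha1 = np.ones((G, I)) if self.spec.class_specific_alpha else np.ones(I)
        self.log_mdp = np.full(S, np.log(1.3)) if self.cd else None
        self.beta = np.zeros((G, I))
        if J > 2:
            base = np.linspace(-0.5, 0.5, J - 1)
        else:
            base = np.zeros(1)
        self.tau = np.tile(base, (1 if self.spec.shared_tau else I, 1))
        # class distributions
        self.mu_theta = np.zeros((G, S))
        self.var_theta = np.ones((G, S))
        self.mu_omega = centers.copy()
        self.var_omega = np.full(G, 0.25)
        self.pi = np.asarray(
            [0.5] + [0.5 / (G - 1)] * (G - 1) if G > 1 else [1.0], dtype=float
        )

    # -- likelihood --------------------------------------------------------

    def _alpha2(self, alpha1: np.ndarray, log_mdp: np.ndarray) -> np.ndarray:
        a1 = alpha1 if alpha1.ndim == 1 else alpha1[0]
        mdp = np.exp(log_mdp)[self.sub]
        return np.sqrt(np.clip(mdp**2 - a1**2, 0.0, None))

    def _omega_eff(self, labels: np.ndarray, log_omega: np.ndarray) -> np.ndarray:
        if not self.spec.omega_free:
            return np.ones(self.N)
        if self.single_free_omega:
            return np.exp(log_omega)
        return np.where(labels == 0, 1.0, np.exp(log_omega))

    def _pointwise_ll(
        self,
        theta: Optional[np.ndarray] = None,
        labels: Optional[np.ndarray] = None,
        log_omega: Optional[np.ndarray] = None,
        alpha1: Optional[np.ndarray] = None,
        beta: Optional[np.ndarray] = None,
        tau: Optional[np.ndarray] = None,
        log_mdp: Optional[np.ndarray] = None,
        mask: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """(N, I) log-probability of each observed response (rows of ``mask`` only)."""
        theta = self.theta if theta is None else theta
        labels = self.labels if labels is None else labels
        log_omega = self.log_omega if log_omega is None else log_omega
        alpha1 = self.alpha1 if alpha1 is None else alpha1
        beta = self.beta if beta is None else beta
        tau = self.tau if tau is None else tau
        log_mdp = self.log_mdp if log_mdp is None else log_mdp
        y = self.y
        if mask is not None:
            theta, labels, log_omega, y = theta[mask], labels[mask], log_omega[mask], y[mask]
        omega = self._omega_eff_subset(labels, log_omega)
        if self.cd:
            W = np.power(omega[:, None], self._alpha2(alpha1, log_mdp)[None, :])
        else:
            W = np.broadcast_to(omega[:, None], (len(omega), self.I))
        A = (alpha1[labels] if alpha1.ndim == 2 else alpha1[None, :]) * theta[:, self.sub]
        tau_items = tau if tau.shape[0] == self.I else np.broadcast_to(tau, (self.I, tau.shape[1]))
        z = A[:, :, None] - (beta[labels][:, :, None] + W[:, :, None] * tau_items[None])
        cum = np.concatenate([np.zeros(z.shape[:2] + (1,)), np.cumsum(z, axis=2)], axis=2)
        mx = cum.max(axis=2, keepdims=True)
        lse = np.log(np.exp(cum - mx).sum(axis=2)) + mx[..., 0]
        picked = np.take_along_axis(cum, y[:, :, None], axis=2)[..., 0]
        return picked - lse

    def _omega_eff_subset(self, labels: np.ndarray, log_omega: np.ndarray) -> np.ndarray:
        if not self.spec.omega_free:
            return np.ones(len(labels))
        if self.single_free_omega:
            return np.exp(log_omega)
        return np.where(labels == 0, 1.0, np.exp(log_omega))

    # -- updates -----------------------------------------------------------

    def _pseudo_logpdf(self, x: np.ndarray) -> np.ndarray:
        s2 = self.priors.pseudo_omega_logsd**2
        centers = self.priors.omega_centers(max(self.G, 3))[1:3]
        comp = np.stack(
            [-0.5 * ((x - c) ** 2 / s2 + np.log(2 * np.pi * s2)) for c in centers]
        )
        mx = comp.max(axis=0)
        return mx + np.log(np.exp(comp - mx).mean(axis=0))

    def _pseudo_draw(self, n: int) -> np.ndarray:
        centers = self.priors.omega_centers(max(self.G, 3))[1:3]
        pick = centers[self.rng.integers(0, len(centers), size=n)]
        return pick + self.priors.pseudo_omega_logsd * self.rng.standard_normal(n)

    def step_classes(self) -> None:
        N, G = self.N, self.G
        ll = np.empty((N, G))
        for g in range(G):
            lbg = np.full(N, g)
            ll_g = self._pointwise_ll(labels=lbg).sum(axis=1)
            th_prior = -0.5 * (
                ((self.theta - self.mu_theta[g]) ** 2 / self.var_theta[g])
                + np.log(2 * np.pi * self.var_theta[g])
            ).sum(axis=1)
            if g == 0:
                om_prior = self._pseudo_logpdf(self.log_omega)
            else:
                v = self.var_omega[g]
                om_prior = -0.5 * (
                    (self.log_omega - self.mu_omega[g]) ** 2 / v + np.log(2 * np.pi * v)
                )
            ll[:, g] = np.log(self.pi[g]) + ll_g + th_prior + om_prior
        ll -= ll.max(axis=1, keepdims=True)
        probs = np.exp(ll)
        probs /= probs.sum(axis=1, keepdims=True)
        self.class_probs = probs
        u = self.rng.random(N)
        self.labels = (u[:, None] > probs.cumsum(axis=1)[:, :-1]).sum(axis=1)
        # refresh the pseudo-prior variable for persons now in the normal class
        normal = self.labels == 0
        self.log_omega[normal] = self._pseudo_draw(int(normal.sum()))

    def step_theta(self) -> None:
        N, S = self.N, self.S
        prop = self.theta + self.steps["theta"] * self.rng.standard_normal((N, S))
        ll_cur = self._pointwise_ll()
        ll_prop = self._pointwise_ll(theta=prop)
        mu = self.mu_theta[self.labels]
        var = self.var_theta[self.labels]
        logr = np.empty((N, S))
        for s in range(S):
            cols = self.sub == s
            logr[:, s] = ll_prop[:, cols].sum(axis=1) - ll_cur[:, cols].sum(axis=1)
        logr += -0.5 * (prop - mu) ** 2 / var + 0.5 * (self.theta - mu) ** 2 / var
        acc = np.log(self.rng.random((N, S))) < logr
        self.theta = np.where(acc, prop, self.theta)
        self.accepts["theta"].append(float(acc.mean()))

    def step_omega(self) -> None:
        if not self.spec.omega_free:
            return
        free = np.ones(self.N, bool) if self.single_free_omega else self.labels > 0
        if not free.any():
            return
        prop = self.log_omega + self.steps["omega"] * self.rng.standard_normal(self.N)
        ll_cur = self._pointwise_ll(mask=free).sum(axis=1)
        ll_prop = self._pointwise_ll(log_omega=prop, mask=free).sum(axis=1)
        mu = self.mu_omega[self.labels[free]]
        var = self.var_omega[self.labels[free]]
        x0, x1 = self.log_omega[free], prop[free]
        logr = ll_prop - ll_cur - 0.5 * (x1 - mu) ** 2 / var + 0.5 * (x0 - mu) ** 2 / var
        acc = np.log(self.rng.random(int(free.sum()))) < logr
        new = self.log_omega.copy()
        new[free] = np.where(acc, x1, x0)
        self.log_omega = new
        self.accepts["omega"].append(float(acc.mean()))

    def step_alpha(self) -> None:
        if not self.spec.alpha_free:
            return
        v = self.priors.slope_logvar
        if self.alpha1.ndim == 1:
            x = np.log(self.alpha1)
            xp = x + self.steps["alpha"] * self.rng.standard_normal(self.I)
            prop = np.exp(xp)
            valid = np.ones(self.I, bool)
            if self.cd:
                valid = prop <= np.exp(self.log_mdp)[self.sub]
            ll_cur = self._pointwise_ll().sum(axis=0)
            ll_prop = self._pointwise_ll(alpha1=prop).sum(axis=0)
            logr = ll_prop - ll_cur - 0.5 * xp**2 / v + 0.5 * x**2 / v
            acc = valid & (np.log(self.rng.random(self.I)) < logr)
            self.alpha1 = np.where(acc, prop, self.alpha1)
            self.accepts["alpha"].append(float(acc.mean()))
        else:  # class-specific discriminations
            rates = []
            for g in range(self.G):
                x = np.log(self.alpha1[g])
                xp = x + self.steps["alpha"] * self.rng.standard_normal(self.I)
                prop_full = self.alpha1.copy()
                prop_full[g] = np.exp(xp)
                mask = self.labels == g
                if mask.any():
                    ll_cur = self._pointwise_ll(mask=mask).sum(axis=0)
                    ll_prop = self._pointwise_ll(alpha1=prop_full, mask=mask).sum(axis=0)
                else:
                    ll_cur = ll_prop = np.zeros(self.I)
                logr = ll_prop - ll_cur - 0.5 * xp**2 / v + 0.5 * x**2 / v
                acc = np.log(self.rng.random(self.I)) < logr
                self.alpha1[g] = np.where(acc, prop_full[g], self.alpha1[g])
                rates.append(float(acc.mean()))
            self.accepts["alpha"].append(float(np.mean(rates)))

    def step_mdp(self) -> None:
        if not self.cd:
            return
        v = self.priors.slope_logvar
        xp = self.log_mdp + self.steps["mdp"] * self.rng.standard_normal(self.S)
        a1 = self.alpha1 if self.alpha1.ndim == 1 else self.alpha1[0]
        ll_cur = self._pointwise_ll().sum(axis=0)
        ll_prop = self._pointwise_ll(log_mdp=xp).sum(axis=0)
        accs = []
        for s in range(self.S):
            cols = self.sub == s
            if np.exp(xp[s]) < a1[cols].max():
                accs.append(0.0)
                continue
            logr = (
                ll_prop[cols].sum()
                - ll_cur[cols].sum()
                - 0.5 * xp[s] ** 2 / v
                + 0.5 * self.log_mdp[s] ** 2 / v
            )
            if np.log(self.rng.random()) < logr:
                self.log_mdp[s] = xp[s]
                accs.append(1.0)
            else:
                accs.append(0.0)
        self.accepts["mdp"].append(float(np.mean(accs)))

    def step_beta(self) -> None:
        v = self.priors.location_var
        n_pairs = self.I // 2
        if n_pairs == 0:
            return
        rates = []
        for g in range(self.G):
            perm = self.rng.permutation(self.I)
            pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2)
            delta = self.steps["beta"] * self.rng.standard_normal(n_pairs)
            prop = self.beta.copy()
            prop[g, pairs[:, 0]] += delta
            prop[g, pairs[:, 1]] -= delta
            mask = self.labels == g
            if mask.any():
                ll_cur = self._pointwise_ll(mask=mask).sum(axis=0)
                ll_prop = self._pointwise_ll(beta=prop, mask=mask).sum(axis=0)
            else:
                ll_cur = ll_prop = np.zeros(self.I)
            dll = (ll_prop - ll_cur)[pairs].sum(axis=1)
            dprior = (
                -0.5 * (prop[g, pairs] ** 2).sum(axis=1) / v
                + 0.5 * (self.beta[g, pairs] ** 2).sum(axis=1) / v
            )
            acc = np.log(self.rng.random(n_pairs)) < dll + dprior
            for p in np.where(acc)[0]:
                self.beta[g, pairs[p]] = prop[g, pairs[p]]
            rates.append(float(acc.mean()))
        self.accepts["beta"].append(float(np.mean(rates)))

    def step_tau(self) -> None:
        K = self.J - 1
        if K < 2:
            return
        v = self.priors.threshold_var
        if self.spec.shared_tau:
            pair = self.rng.choice(K, 2, replace=False)
            delta = self.steps["tau"] * self.rng.standard_normal()
            prop = self.tau.copy()
            prop[0, pair[0]] += delta
            prop[0, pair[1]] -= delta
            ll_cur = self._pointwise_ll().sum()
            ll_prop = self._pointwise_ll(tau=prop).sum()
            logr = (
                ll_prop - ll_cur
                - 0.5 * (prop[0, pair] ** 2).sum() / v
                + 0.5 * (self.tau[0, pair] ** 2).sum() / v
            )
            acc = np.log(self.rng.random()) < logr
            if acc:
                self.tau = prop
            self.accepts["tau"].append(float(acc))
            return
        idx = np.argsort(self.rng.random((self.I, K)), axis=1)[:, :2]
        delta = self.steps["tau"] * self.rng.standard_normal(self.I)
        prop = self.tau.copy()
        rows = np.arange(self.I)
        prop[rows, idx[:, 0]] += delta
        prop[rows, idx[:, 1]] -= delta
        ll_cur = self._pointwise_ll().sum(axis=0)
        ll_prop = self._pointwise_ll(tau=prop).sum(axis=0)
        dprior = (
            -0.5 * (prop[rows[:, None], idx] ** 2).sum(axis=1) / v
            + 0.5 * (self.tau[rows[:, None], idx] ** 2).sum(axis=1) / v
        )
        acc = np.log(self.rng.random(self.I)) < (ll_prop - ll_cur + dprior)
        self.tau = np.where(acc[:, None], prop, self.tau)
        self.accepts["tau"].append(float(acc.mean()))

    # Latent variances are truncated to [1e-4, 4] (log-omega and theta scale):
    # with the vague Gamma(0.01, 0.01) precision prior an accidentally emptied
    # class would otherwise draw an enormous variance, assign ~zero density to
    # every respondent, and die permanently.  The cap is far above any
    # plausible posterior value, so it only matters in that degenerate state.
    _VAR_LO, _VAR_HI = 1e-4, 4.0

    def step_class_dists(self) -> None:
        pr, rng = self.priors, self.rng
        a0, b0 = pr.precision_shape, pr.precision_rate
        for g in range(1, self.G):
            mask = self.labels == g
            n = int(mask.sum())
            for s in range(self.S):
                x = self.theta[mask, s]
                prec = n / self.var_theta[g, s] + 1.0 / pr.class_theta_mean_var
                mean = (x.sum() / self.var_theta[g, s]) / prec
                self.mu_theta[g, s] = mean + rng.standard_normal() / np.sqrt(prec)
                ssq = ((x - self.mu_theta[g, s]) ** 2).sum()
                precision = rng.gamma(a0 + n / 2.0) / (b0 + ssq / 2.0)
                self.var_theta[g, s] = float(np.clip(1.0 / precision, self._VAR_LO, self._VAR_HI))
            x = self.log_omega[mask]
            center = pr.omega_centers(self.G)[g]
            prec = n / self.var_omega[g] + 1.0 / pr.omega_logmean_var
            mean = (x.sum() / self.var_omega[g] + center / pr.omega_logmean_var) / prec
            self.mu_omega[g] = mean + rng.standard_normal() / np.sqrt(prec)
            ssq = ((x - self.mu_omega[g]) ** 2).sum()
            precision = rng.gamma(a0 + n / 2.0) / (b0 + ssq / 2.0)
            self.var_omega[g] = float(np.clip(1.0 / precision, self._VAR_LO, self._VAR_HI))
        if self.single_free_omega:
            x = self.log_omega
            ssq = (x**2).sum()  # log-mean pinned at zero
            precision = rng.gamma(a0 + self.N / 2.0) / (b0 + ssq / 2.0)
            self.var_omega[0] = float(np.clip(1.0 / precision, self._VAR_LO, self._VAR_HI))

    def step_mixing(self) -> None:
        counts = np.bincount(self.labels, minlength=self.G)
        conc = self.priors.mixing_concentration + counts
        for _ in range(100):
            p = self.rng.dirichlet(conc)
            if self.G == 1 or p[0] >= p[1:].max():
                self.pi = p
                return
        # ordering rejection failed; keep the current (valid) value

    def _adapt(self, t: int) -> None:
        gamma = min(0.25, 2.0 / (1 + t) ** 0.55)
        for key, hist in self.accepts.items():
            if hist:
                self.steps[key] *= float(np.exp(gamma * (hist[-1] - 0.44)))
                self.steps[key] = float(np.clip(self.steps[key], 1e-3, 5.0))

    # class labels stay at their starting assignment for the first burn-in
    # iterations so person/item parameters can adapt before classes compete
    _CLASS_FREEZE = 25

    def iterate(self, t: int, burnin: bool) -> None:
        if self.G > 1 and t >= self._CLASS_FREEZE:
            self.step_classes()
        self.step_theta()
        self.step_omega()
        self.step_alpha()
        self.step_mdp()
        self.step_beta()
        self.step_tau()
        self.step_class_dists()
        if self.G > 1:
            self.step_mixing()
        if burnin:
            self._adapt(t)

    # -- recording ---------------------------------------------------------

    def snapshot(self) -> Dict[str, np.ndarray]:
        snap = {
            "alpha1": self.alpha1.copy(),
            "beta": self.beta.copy(),
            "tau": self.tau.copy(),
            "mu_theta": self.mu_theta.copy(),
            "var_theta": self.var_theta.copy(),
            "mu_omega": self.mu_omega.copy(),
            "var_omega": self.var_omega.copy(),
            "pi": self.pi.copy(),
        }
        if self.cd:
            snap["mdp"] = np.exp(self.log_mdp)
        return snap


def _run_chain(
    y: np.ndarray,
    spec: ModelSpec,
    priors: PriorSpec,
    mcmc: McmcConfig,
    rng: np.random.Generator,
    chain_index: int,
) -> Dict[str, object]:
    smp = _Sampler(y, spec, priors, rng, chain_index)
    N, S, G = smp.N, smp.S, smp.G
    draws: Dict[str, List[np.ndarray]] = {}
    theta_sum = np.zeros((N, S))
    theta_sq = np.zeros((N, S))
    omega_sum = np.zeros(N)
    omega_sq = np.zeros(N)
    member_sum = np.zeros((N, G))
    person_draws: Dict[str, List[np.ndarray]] = (
        {"omega_eff": [], "labels": [], "theta": []} if mcmc.store_person_draws else {}
    )
    n_kept = 0
    for t in range(mcmc.n_iterations):
        burnin = t < mcmc.n_burnin
        smp.iterate(t, burnin and mcmc.adapt)
        if burnin or (t - mcmc.n_burnin) % mcmc.thinning:
            continue
        n_kept += 1
        for k, v in smp.snapshot().items():
            draws.setdefault(k, []).append(v)
        theta_sum += smp.theta
        theta_sq += smp.theta**2
        om = smp._omega_eff(smp.labels, smp.log_omega)
        omega_sum += om
        omega_sq += om**2
        if G > 1:
            member_sum += smp.class_probs
        else:
            member_sum += 1.0
        if mcmc.store_person_draws:
            person_draws["omega_eff"].append(om.copy())
            person_draws["labels"].append(smp.labels.copy())
            person_draws["theta"].append(smp.theta.copy())
    out: Dict[str, object] = {
        "draws": {k: np.stack(v) for k, v in draws.items()},
        "theta_sum": theta_sum,
        "theta_sq": theta_sq,
        "omega_sum": omega_sum,
        "omega_sq": omega_sq,
        "member_sum": member_sum,
        "n_kept": n_kept,
        "acceptance": {k: float(np.mean(v)) if v else np.nan for k, v in smp.accepts.items()},
        "steps": dict(smp.steps),
    }
    if mcmc.store_person_draws:
        out["person_draws"] = {k: np.stack(v) for k, v in person_draws.items()}
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics


def psrf(chains: Union[np.ndarray, Sequence[np.ndarray]]) -> float:
    """Brooks–Gelman multivariate potential scale reduction factor.

    ``chains`` is an (m, n, p) array (m chains, n draws, p parameters) or a
    sequence of (n, p) arrays.  Values close to 1 indicate convergence.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("chains must be (m, n, p)")
    m, n, p = arr.shape
    if m < 2:
        raise ValueError("at least two chains are required for the PSRF")
    means = arr.mean(axis=1)  # (m, p)
    W = np.zeros((p, p))
    for j in range(m):
        d = arr[j] - means[j]
        W += d.T @ d / (n - 1)
    W /= m
    gm = means.mean(axis=0)
    Bn = (means - gm).T @ (means - gm) / (m - 1)  # B/n
    W = W + 1e-10 * np.eye(p)
    from scipy.linalg import eigh

    lam = eigh(Bn, W, eigvals_only=True, subset_by_index=(p - 1, p - 1))[0]
    return float((n - 1) / n + (m + 1) / m * lam)


def psrf_univariate(chains: Union[np.ndarray, Sequence[np.ndarray]]) -> np.ndarray:
    """Classic Gelman–Rubin PSRF per parameter column."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, p = arr.shape
    if m < 2:
        raise ValueError("at least two chains are required for the PSRF")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt((m + 1) / m * vhat / W - (n - 1) / (m * n))
    return np.where(W > 0, r, 1.0)


def _free_vector(draws: Dict[str, np.ndarray], spec: ModelSpec) -> Dict[str, np.ndarray]:
    """Per-block (n_draws, p) matrices of free (non-redundant) coordinates."""
    blocks: Dict[str, np.ndarray] = {}
    D = draws["beta"].shape[0]
    if spec.alpha_free:
        blocks["alpha"] = np.log(draws["alpha1"]).reshape(D, -1)
    blocks["beta"] = draws["beta"][:, :, :-1].reshape(D, -1)
    if spec.n_categories > 2:
        blocks["tau"] = draws["tau"][:, :, :-1].reshape(D, -1)
    if "mdp" in draws:
        blocks["mdp"] = np.log(draws["mdp"]).reshape(D, -1)
    if spec.n_classes > 1:
        blocks["class_dists"] = np.concatenate(
            [
                draws["mu_theta"][:, 1:].reshape(D, -1),
                np.log(draws["var_theta"][:, 1:]).reshape(D, -1),
                draws["mu_omega"][:, 1:].reshape(D, -1),
                np.log(draws["var_omega"][:, 1:]).reshape(D, -1),
            ],
            axis=1,
        )
        blocks["mixing"] = draws["pi"][:, :-1].reshape(D, -1)
    elif spec.omega_free:
        blocks["class_dists"] = np.log(draws["var_omega"][:, :1]).reshape(D, -1)
    return blocks


# ---------------------------------------------------------------------------
# fitting


def fit(
    responses: Union[ResponseMatrix, np.ndarray],
    model_spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
) -> PosteriorSummary:
    """Fit one model to a response matrix and summarize the posterior.

    Runs ``mcmc.n_chains`` independent chains from jittered starting points,
    discards the burn-in, pools retained draws for EAP/SD summaries, and (with
    at least two chains) computes per-block and overall multivariate PSRFs.
    Non-convergence (any PSRF above the threshold) is flagged with a warning,
    never silently accepted.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    if y.ndim != 2:
        raise ValueError("responses must be an N x I matrix")
    if y.min() < 0 or y.max() >= model_spec.n_categories:
        raise ValueError("responses outside the declared category range")
    N, I = y.shape
    if model_spec.n_classes > 1 and (N < 1000 or I < 20):
        warnings.warn(
            "mixture ERS models are unreliable below ~1000 respondents and ~20 items; "
            f"got N={N}, I={I}",
            UserWarning,
            stacklevel=2,
        )
    ss = np.random.SeedSequence(mcmc.seed)
    chain_results = [
        _run_chain(y, model_spec, priors, mcmc, np.random.default_rng(child), c)
        for c, child in enumerate(ss.spawn(mcmc.n_chains))
    ]
    pooled = {
        k: np.concatenate([cr["draws"][k] for cr in chain_results])
        for k in chain_results[0]["draws"]
    }
    eap = {k: v.mean(axis=0) for k, v in pooled.items()}
    sd = {k: v.std(axis=0, ddof=1) for k, v in pooled.items()}
    total = sum(cr["n_kept"] for cr in chain_results)
    theta_sum = sum(cr["theta_sum"] for cr in chain_results)
    theta_sq = sum(cr["theta_sq"] for cr in chain_results)
    omega_sum = sum(cr["omega_sum"] for cr in chain_results)
    omega_sq = sum(cr["omega_sq"] for cr in chain_results)
    member = sum(cr["member_sum"] for cr in chain_results) / total
    theta_eap = theta_sum / total
    theta_sd = np.sqrt(np.clip(theta_sq / total - theta_eap**2, 0.0, None))
    omega_eap = omega_sum / total
    omega_sd = np.sqrt(np.clip(omega_sq / total - omega_eap**2, 0.0, None))
    if theta_eap.shape[1] == 1:
        theta_eap, theta_sd = theta_eap[:, 0], theta_sd[:, 0]
    psrf_vals: Dict[str, float] = {}
    converged: Optional[bool] = None
    if mcmc.n_chains >= 2:
        per_chain_blocks = [_free_vector(cr["draws"], model_spec) for cr in chain_results]
        for name in per_chain_blocks[0]:
            stack = np.stack([b[name] for b in per_chain_blocks])
            try:
                psrf_vals[name] = psrf(stack)
            except np.linalg.LinAlgError:
                psrf_vals[name] = float("nan")
        allp = np.concatenate(
            [np.stack([b[name] for b in per_chain_blocks]) for name in per_chain_blocks[0]],
            axis=2,
        )
        try:
            psrf_vals["multivariate"] = psrf(allp)
        except np.linalg.LinAlgError:
            psrf_vals["multivariate"] = max(psrf_vals.values())
        converged = all(v <= mcmc.psrf_threshold for v in psrf_vals.values() if np.isfinite(v))
        if not converged:
            warnings.warn(
                f"chains not converged: PSRF {psrf_vals}", UserWarning, stacklevel=2
            )
    acceptance = {}
    for k in chain_results[0]["acceptance"]:
        vals = [cr["acceptance"][k] for cr in chain_results if np.isfinite(cr["acceptance"][k])]
        if vals:
            acceptance[k] = float(np.mean(vals))
    person_draws = None
    if mcmc.store_person_draws:
        person_draws = {
            k: np.concatenate([cr["person_draws"][k] for cr in chain_results])
            for k in chain_results[0]["person_draws"]
        }
    summary = PosteriorSummary(
        model_spec=model_spec,
        mcmc=mcmc,
        eap=eap,
        sd=sd,
        theta_eap=theta_eap,
        theta_sd=theta_sd,
        omega_eap=omega_eap,
        omega_sd=omega_sd,
        membership_probs=member,
        chains=[cr["draws"] for cr in chain_results],
        psrf=psrf_vals,
        converged=converged,
        loglik_at_eap=float("nan"),
        acceptance=acceptance,
        person_draws=person_draws,
    )
    summary.loglik_at_eap = marginal_loglik(y, eap_item_parameters(summary),
                                            eap_class_spec(summary), cd=model_spec.is_cd)
    return summary


def eap_item_parameters(posterior: PosteriorSummary) -> ItemParameters:
    """EAP point estimates assembled into an :class:`ItemParameters` bank."""
    spec = posterior.model_spec
    eap = posterior.eap
    alpha1 = eap["alpha1"] if eap["alpha1"].ndim == 1 else eap["alpha1"][0]
    I = alpha1.shape[0]
    tau = eap["tau"]
    if tau.shape[0] == 1 and I > 1:
        tau = np.tile(tau, (I, 1))
    mdp = eap.get("mdp")
    alpha2 = None
    if mdp is not None:
        sub = spec.subscale_of_item if spec.subscale_of_item is not None else np.zeros(I, int)
        alpha2 = np.sqrt(np.clip(mdp[sub] ** 2 - alpha1**2, 0.0, None))
    return ItemParameters(
        alpha1=alpha1,
        beta=eap["beta"],
        tau=tau,
        alpha2=alpha2,
        mdp=mdp,
        subscale_of_item=spec.subscale_of_item,
    )


def eap_class_spec(posterior: PosteriorSummary) -> ClassSpec:
    """EAP class mixing and latent-distribution parameters (identified values)."""
    eap = posterior.eap
    G = eap["pi"].shape[0]
    mu_th = eap["mu_theta"].copy()
    var_th = eap["var_theta"].copy()
    mu_th[0], var_th[0] = 0.0, 1.0
    mu_om = eap["mu_omega"].copy()
    var_om = eap["var_omega"].copy()
    mu_om[0] = 0.0
    if G > 1:
        var_om[0] = 0.0
    pi = eap["pi"] / eap["pi"].sum()
    return ClassSpec(
        mixing=pi,
        theta_mean=mu_th,
        theta_var=var_th,
        omega_logmean=mu_om,
        omega_logvar=var_om,
    )


# ---------------------------------------------------------------------------
# classification


def classify(posterior: Union[PosteriorSummary, np.ndarray]) -> np.ndarray:
    """Modal class per respondent; exact ties go to the normal class (index 0)."""
    probs = (
        posterior.membership_probs if isinstance(posterior, PosteriorSummary) else np.asarray(posterior)
    )
    labels = probs.argmax(axis=1)
    top = probs.max(axis=1)
    labels[np.abs(probs[:, 0] - top) < 1e-12] = 0
    return labels


def naive_ers_classify(omega_hat, se) -> np.ndarray:
    """Wald-type style classifier from a single-class ERS fit.

    The statistic ``(omega_hat - 1) / se`` is compared with +-1.96: below
    -1.96 -> ERS (1), above +1.96 -> MRS (2), otherwise normal (0).
    """
    scalar = np.isscalar(omega_hat) or np.ndim(omega_hat) == 0
    omega_hat = np.atleast_1d(np.asarray(omega_hat, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    stat = (omega_hat - 1.0) / se
    out = np.zeros(stat.shape, dtype=int)
    out[stat < -1.96] = 1
    out[stat > 1.96] = 2
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# marginal likelihood and BIC


def _theta_moments(classes: ClassSpec, S: int) -> Tuple[np.ndarray, np.ndarray]:
    mu = np.asarray(classes.theta_mean, dtype=float)
    var = np.asarray(classes.theta_var, dtype=float)
    if mu.ndim == 1:
        mu = mu[:, None] * np.ones((1, S))
        var = var[:, None] * np.ones((1, S))
    return mu, var


def marginal_loglik(
    responses: Union[ResponseMatrix, np.ndarray],
    items: ItemParameters,
    classes: ClassSpec,
    cd: bool = False,
    n_quad: int = 15,
) -> float:
    """Observed-data log-likelihood with person effects integrated out.

    Class membership is summed out; theta (per subscale) and log omega are
    integrated by Gauss–Hermite quadrature with ``n_quad`` nodes per
    dimension, centered at each class's latent distribution.  The normal
    class (and any class with zero omega variance) needs no omega dimension.
    """
    y = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    N, I = y.shape
    G = classes.n_classes
    S = items.n_subscales
    sub = items.subscale_of_item
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    mu_th, var_th = _theta_moments(classes, S)
    alpha2 = items.effective_alpha2() if cd else None
    lp_class = np.full((N, G), -np.inf)
    for g in range(G):
        omega_fixed = (G > 1 and g == 0) or classes.omega_logvar[g] <= 0
        if omega_fixed:
            om_nodes = np.array([np.exp(classes.omega_logmean[g])])
            om_logw = np.array([0.0])
        else:
            x = classes.omega_logmean[g] + np.sqrt(2 * classes.omega_logvar[g]) * nodes
            om_nodes = np.exp(x)
            om_logw = logw
        acc = np.zeros((len(om_nodes), N))
        for k, om in enumerate(om_nodes):
            for s in range(S):
                cols = np.where(sub == s)[0]
                th = mu_th[g, s] + np.sqrt(2 * var_th[g, s]) * nodes  # (K,)
                w_i = om ** alpha2[cols] if cd else np.full(len(cols), om)
                z = (
                    items.alpha1[cols][None, :, None] * th[:, None, None]
                    - (items.beta[g, cols][None, :, None] + w_i[None, :, None] * items.tau[cols][None])
                )
                cum = np.concatenate([np.zeros(z.shape[:2] + (1,)), np.cumsum(z, axis=2)], axis=2)
                logp = cum - logsumexp(cum, axis=2, keepdims=True)  # (K, Is, J)
                ll_kni = logp[:, np.arange(len(cols))[None, :], y[:, cols]]  # (K, N, Is)
                ll_kn = ll_kni.sum(axis=2)  # (K, N)
                acc[k] += logsumexp(ll_kn + logw[:, None], axis=0)
        lp_class[:, g] = logsumexp(acc + om_logw[:, None], axis=0)
    lp = logsumexp(lp_class + np.log(classes.mixing)[None, :], axis=1)
    return float(lp.sum())


def bic(
    posterior: PosteriorSummary,
    responses: Union[ResponseMatrix, np.ndarray],
    model_spec: Optional[ModelSpec] = None,
    n_quad: int = 15,
) -> float:
    """BIC = -2 logL + k log N at the EAP parameter values.

    ``logL`` is the observed-data likelihood (classes summed out, person
    effects integrated by quadrature); ``k`` counts free structural
    parameters only.
    """
    model_spec = model_spec or posterior.model_spec
    y = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    items = eap_item_parameters(posterior)
    classes = eap_class_spec(posterior)
    ll = marginal_loglik(y, items, classes, cd=model_spec.is_cd, n_quad=n_quad)
    if not np.isfinite(ll):
        raise ValueError("non-finite marginal likelihood")
    k = model_spec.n_free_parameters(items.n_items)
    return float(-2.0 * ll + k * np.log(y.shape[0]))
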