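"""Synthetic rating-scale data under the ERS mixture model family.

The default design reproduces the generating conditions of the recovery
studies this package is built around: three latent classes (normal / ERS /
MRS) with proportions 0.50 / 0.25 / 0.25; theta ~ N(0, 1) in every class;
omega fixed at 1 for the normal class and drawn lognormal(-1, 0.4^2) for the
ERS class and lognormal(1, 0.4^2) for the MRS class; item discriminations
lognormal(0, 0.2^2); normal-class overall difficulties uniform(-1.5, 1.5)
centered to mean zero; style-class difficulties shifted by a balanced +-0.5
so every class keeps the same mean difficulty; fixed centered threshold
grids (-0.6, 0, 0.6) for 4-point and (-0.8, -0.4, 0, 0.4, 0.8) for 6-point
items.  The CD variant fixes the total discrimination MDP = 1.50 and splits
it as alpha1**2 + alpha2**2 = MDP**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    ClassSpec,
    ItemParameters,
    PersonState,
    alpha2_from_mdp,
    adjacent_logits_to_probs,
)

__all__ = [
    "SimulationDesign",
    "ResponseMatrix",
    "default_tau_grid",
    "generate_item_bank",
    "generate_persons",
    "simulate_responses",
    "simulate_dataset",
]


def default_tau_grid(n_categories: int) -> np.ndarray:
    """The fixed threshold grids used in the recovery studies."""
    if n_categories == 4:
        return np.array([-0.6, 0.0, 0.6])
    if n_categories == 6:
        return np.array([-0.8, -0.4, 0.0, 0.4, 0.8])
    # other category counts: equally spaced, centered, matching the 4/6 spacing
    half = 0.2 * (n_categories - 1)
    return np.linspace(-half, half, n_categories - 1)


@dataclass
class SimulationDesign:
    """Design of one simulated condition.

    ``class_proportions[0]`` is the normal class and must dominate.
    ``omega_dists`` gives (meanlog, sdlog) of the lognormal omega distribution
    per style class; the normal class is implicitly fixed at omega = 1.
    ``class_beta_shift`` is added to half the items (subtracted from the other
    half) per style class so mean difficulty stays equal across classes.
    ``mdp`` switches generation to the CD model.
    """

    n_respondents: int = 1000
    n_items: int = 20
    n_categories: int = 4
    class_proportions: Tuple[float, ...] = (0.50, 0.25, 0.25)
    omega_dists: Tuple[Tuple[float, float], ...] = ((-1.0, 0.4), (1.0, 0.4))
    alpha1_dist: Tuple[float, float] = (0.0, 0.2)  # (meanlog, sdlog)
    beta_range: Tuple[float, float] = (-1.5, 1.5)
    class_beta_shift: float = 0.5
    tau_grid: Optional[Sequence[float]] = None
    mdp: Optional[float] = None
    n_subscales: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        if np.any(props[0] + 1e-12 < props[1:]):
            raise ValueError("normal class proportion must dominate")
        if len(self.omega_dists) != len(self.class_proportions) - 1:
            raise ValueError("one omega distribution required per style class")
        if self.tau_grid is None:
            self.tau_grid = default_tau_grid(self.n_categories)
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        if self.tau_grid.shape[0] != self.n_categories - 1:
            raise ValueError("tau_grid must have n_categories - 1 entries")
        if not np.isclose(self.tau_grid.mean(), 0.0):
            raise ValueError("tau_grid must be centered (mean zero)")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def class_spec(self) -> ClassSpec:
        G = self.n_classes
        mus = np.zeros(G)
        sds = np.zeros(G)
        for g, (m, s) in enumerate(self.omega_dists, start=1):
            mus[g], sds[g] = m, s
        return ClassSpec(
            mixing=np.asarray(self.class_proportions, dtype=float),
            theta_mean=np.zeros(G),
            theta_var=np.ones(G),
            omega_logmean=mus,
            omega_logvar=sds**2,
        )


@dataclass
class ResponseMatrix:
    """N x I ordered responses, categories 0 .. J-1, with optional attached truth."""

    responses: np.ndarray
    n_categories: int
    items: Optional[ItemParameters] = None
    persons: Optional[List[PersonState]] = None
    classes: Optional[ClassSpec] = None
    model: Optional[str] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be an N x I matrix")
        if self.responses.min() < 0 or self.responses.max() >= self.n_categories:
            raise ValueError("responses outside 0 .. J-1")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def true_theta(self) -> np.ndarray:
        return np.array([p.theta if p.theta.size > 1 else p.theta[0] for p in self.persons])

    def true_omega(self) -> np.ndarray:
        return np.array(
            [1.0 if p.class_label == 0 else p.omega for p in self.persons]
        )

    def true_classes(self) -> np.ndarray:
        return np.array([p.class_label for p in self.persons], dtype=int)

    def subset(self, n: int) -> "ResponseMatrix":
        """First-n-respondents subsample (common-random-number comparisons)."""
        persons = self.persons[:n] if self.persons is not None else None
        return ResponseMatrix(
            self.responses[:n], self.n_categories, self.items, persons, self.classes, self.model
        )


# ---------------------------------------------------------------------------
# generators


def generate_item_bank(
    design: SimulationDesign, rng: Optional[np.random.Generator] = None
) -> ItemParameters:
    """Draw an item bank for the design.

    Normal-class difficulties are uniform draws centered to mean exactly zero;
    each style class adds a balanced +-shift (half the items up, half down, in
    random order) so all classes share the same mean difficulty.  When the
    design fixes an MDP, alpha1 draws are rejected until alpha1 <= MDP and
    alpha2 follows from the conservation identity.
    """
    rng = design.rng() if rng is None else rng
    I, G = design.n_items, design.n_classes
    meanlog, sdlog = design.alpha1_dist
    alpha1 = rng.lognormal(meanlog, sdlog, size=I)
    if design.mdp is not None:
        for _ in range(1000):
            bad = alpha1 > design.mdp
            if not bad.any():
                break
            alpha1[bad] = rng.lognormal(meanlog, sdlog, size=int(bad.sum()))
        else:
            raise ValueError("alpha1 distribution incompatible with mdp bound")
    lo, hi = design.beta_range
    beta0 = rng.uniform(lo, hi, size=I)
    beta0 -= beta0.mean()
    beta = np.empty((G, I))
    beta[0] = beta0
    for g in range(1, G):
        shifts = np.full(I, design.class_beta_shift)
        shifts[: I // 2] *= -1.0
        if I % 2 == 1:
            shifts[I // 2] = design.class_beta_shift * rng.choice([-1.0, 1.0])
        rng.shuffle(shifts)
        beta[g] = beta0 + shifts - shifts.mean()
    tau = np.tile(design.tau_grid, (I, 1))
    sub = np.arange(I) % design.n_subscales if design.n_subscales > 1 else None
    mdp = None if design.mdp is None else np.full(design.n_subscales, float(design.mdp))
    alpha2 = None if design.mdp is None else alpha2_from_mdp(float(design.mdp), alpha1)
    return ItemParameters(
        alpha1=alpha1, beta=beta, tau=tau, alpha2=alpha2, mdp=mdp, subscale_of_item=sub
    )


def generate_persons(
    design: SimulationDesign, rng: Optional[np.random.Generator] = None
) -> List[PersonState]:
    """Draw class labels, traits and style weights for all respondents."""
    rng = design.rng() if rng is None else rng
    N, G, S = design.n_respondents, design.n_classes, design.n_subscales
    labels = rng.choice(G, size=N, p=np.asarray(design.class_proportions, dtype=float))
    theta = rng.standard_normal((N, S))
    omega = np.ones(N)
    for g, (m, s) in enumerate(design.omega_dists, start=1):
        mask = labels == g
        omega[mask] = rng.lognormal(m, s, size=int(mask.sum()))
    return [
        PersonState(theta=theta[n] if S > 1 else theta[n, 0], omega=omega[n], class_label=int(labels[n]))
        for n in range(N)
    ]


def simulate_responses(
    items: ItemParameters,
    persons: List[PersonState],
    model: str = "mix-ers-gpcm",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    classes: Optional[ClassSpec] = None,
) -> ResponseMatrix:
    """Draw a categorical response for every person-item cell.

    ``model`` is ``"mix-ers-gpcm"`` (thresholds scaled by the raw omega) or
    ``"mix-ers-gpcm-cd"`` (scaled by eta = omega**alpha2).  A fixed seed (or
    generator) makes the output bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if model not in ("mix-ers-gpcm", "mix-ers-gpcm-cd"):
        raise ValueError(f"unknown generating model {model!r}")
    N, I, J = len(persons), items.n_items, items.n_categories
    theta = np.stack([p.theta for p in persons])  # (N, S)
    labels = np.array([p.class_label for p in persons], dtype=int)
    if labels.max() >= items.n_classes:
        raise ValueError("person class without class-specific difficulties")
    omega = np.array([1.0 if p.class_label == 0 else p.omega for p in persons])
    if model == "mix-ers-gpcm-cd":
        weight = np.power(omega[:, None], items.effective_alpha2()[None, :])  # (N, I)
    else:
        weight = np.tile(omega[:, None], (1, I))
    theta_item = theta[:, items.subscale_of_item]  # (N, I)
    z = items.alpha1[None, :, None] * theta_item[:, :, None] - (
        items.beta[labels][:, :, None] + weight[:, :, None] * items.tau[None]
    )
    probs = adjacent_logits_to_probs(z)  # (N, I, J)
    cum = probs.cumsum(axis=-1)
    u = rng.random((N, I, 1))
    resp = (u > cum[..., :-1]).sum(axis=-1)
    return ResponseMatrix(
        responses=resp,
        n_categories=J,
        items=items,
        persons=list(persons),
        classes=classes,
        model=model,
    )


def simulate_dataset(
    design: SimulationDesign, model: Optional[str] = None, seed: Optional[int] = None
) -> ResponseMatrix:
    """Item bank + persons + responses in one call from a single seed."""
    if seed is not None:
        design = SimulationDesign(**{**design.__dict__, "seed": seed, "tau_grid": design.tau_grid})
    rng = design.rng()
    if model is None:
        model = "mix-ers-gpcm-cd" if design.mdp is not None else "mix-ers-gpcm"
    items = generate_item_bank(design, rng)
    persons = generate_persons(design, rng)
    return simulate_responses(items, persons, model=model, rng=rng, classes=design.class_spec())
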