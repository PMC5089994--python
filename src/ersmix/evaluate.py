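"""Recovery metrics, misfit diagnostics, and applied-study summaries.

Bias and RMSE are computed against generating values, averaging over
replications for model parameters and over respondents for person
parameters.  Classification quality is summarized by per-class and pooled
correct classification rates (CCR).  The misfit study quantifies what is
lost when a reduced model (single-class ERS-GPCM, or the plain GPCM) is fit
to data generated under the three-class mixture, including the naive
Wald-test style classifier and the shrinkage pattern of the trait estimates
for misclassified respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.stats import rankdata

from .estimation import (
    McmcConfig,
    ModelSpec,
    PosteriorSummary,
    PriorSpec,
    classify,
    fit,
    naive_ers_classify,
)
from .models import ItemParameters
from .simulate import ResponseMatrix, SimulationDesign, simulate_dataset

__all__ = [
    "RecoveryReport",
    "MisfitReport",
    "bias",
    "rmse",
    "correct_classification_rate",
    "recovery_report",
    "misfit_study",
    "rank_order_change",
    "item_ers_elicitation",
    "replicate_study",
]


def bias(estimates, truth) -> float:
    """Mean estimate minus generating value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(estimates) - truth)


def rmse(estimates, truth) -> float:
    """Root mean squared deviation from the generating value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def correct_classification_rate(assigned, truth) -> Dict[str, float]:
    """Pooled and per-class proportions of correctly recovered class labels.

    Per-class rates use the true-class sizes as denominators; the pooled rate
    is the overall match proportion (equivalently the size-weighted mean of
    the per-class rates).
    """
    assigned = np.asarray(assigned, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if assigned.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    if np.setdiff1d(assigned, np.arange(max(truth.max(), assigned.max()) + 1)).size:
        raise ValueError("label alphabets do not match")
    out = {"overall": float(np.mean(assigned == truth))}
    for g in np.unique(truth):
        mask = truth == g
        out[f"class_{g}"] = float(np.mean(assigned[mask] == g))
    rates = [out[f"class_{g}"] for g in np.unique(truth)]
    out["macro"] = float(np.mean(rates))
    return out


@dataclass
class RecoveryReport:
    """Bias/RMSE/classification summary for one or more replications."""

    n_replications: int
    bias: Dict[str, float]
    rmse: Dict[str, float]
    ccr: Dict[str, float]
    theta_rmse: float
    omega_rmse: float
    confusion: Optional[np.ndarray] = None
    per_replication: List[Dict[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        for k in self.bias:
            if self.rmse[k] + 1e-12 < abs(self.bias[k]):
                raise ValueError(f"RMSE < |bias| for {k}")

    def to_table(self) -> str:
        """Plain-text recovery table (parameter family x bias/RMSE)."""
        lines = [f"{'parameter':<16}{'bias':>10}{'RMSE':>10}"]
        for k in self.bias:
            lines.append(f"{k:<16}{self.bias[k]:>10.3f}{self.rmse[k]:>10.3f}")
        lines.append("")
        lines.append(f"{'Mean RMSE(theta)':<22}{self.theta_rmse:.3f}")
        lines.append(f"{'Mean RMSE(omega)':<22}{self.omega_rmse:.3f}")
        for k, v in self.ccr.items():
            lines.append(f"{'CCR ' + k:<22}{v:.3f}")
        lines.append(f"{'replications':<22}{self.n_replications}")
        return "\n".join(lines)

    def to_json(self) -> str:
        import json

        doc = {
            "n_replications": self.n_replications,
            "bias": self.bias,
            "rmse": self.rmse,
            "ccr": self.ccr,
            "theta_rmse": self.theta_rmse,
            "omega_rmse": self.omega_rmse,
            "confusion": None if self.confusion is None else np.asarray(self.confusion).tolist(),
        }
        return json.dumps(doc, indent=1)


def _person_metrics(
    post: PosteriorSummary, data: ResponseMatrix
) -> Tuple[float, float, Dict[str, float], np.ndarray, np.ndarray]:
    theta_true = data.true_theta()
    omega_true = data.true_omega()
    th = np.asarray(post.theta_eap)
    theta_rmse = float(np.sqrt(np.mean((th - theta_true) ** 2)))
    omega_rmse = float(np.sqrt(np.mean((post.omega_eap - omega_true) ** 2)))
    assigned = classify(post)
    ccr = correct_classification_rate(assigned, data.true_classes())
    G = int(data.true_classes().max()) + 1
    conf = np.zeros((G, G), dtype=int)
    np.add.at(conf, (data.true_classes(), assigned), 1)
    return theta_rmse, omega_rmse, ccr, assigned, conf


def recovery_report(
    posteriors: Union[PosteriorSummary, List[PosteriorSummary]],
    datasets: Union[ResponseMatrix, List[ResponseMatrix]],
) -> RecoveryReport:
    """Recovery summary of one or more fitted replications against truth.

    Model-parameter bias/RMSE pool the per-item (per-class) estimates over
    replications and items, the way recovery tables average within a
    parameter family; person-parameter RMSE averages over respondents, then
    over replications.
    """
    if isinstance(posteriors, PosteriorSummary):
        posteriors, datasets = [posteriors], [datasets]
    R = len(posteriors)
    fam_err: Dict[str, List[float]] = {}
    th_rmse, om_rmse, ccrs, confs, per_rep = [], [], [], [], []
    for post, data in zip(posteriors, datasets):
        items: ItemParameters = data.items
        est_alpha = post.eap["alpha1"]
        if est_alpha.ndim == 2:
            est_alpha = est_alpha[0]
        fam_err.setdefault("discrimination", []).extend(est_alpha - items.alpha1)
        fam_err.setdefault("location", []).extend((post.eap["beta"] - items.beta).ravel())
        est_tau = post.eap["tau"]
        if est_tau.shape[0] == 1:
            est_tau = np.tile(est_tau, (items.n_items, 1))
        fam_err.setdefault("threshold", []).extend((est_tau - items.tau).ravel())
        if "mdp" in post.eap and items.mdp is not None:
            fam_err.setdefault("mdp", []).extend(np.atleast_1d(post.eap["mdp"] - items.mdp))
        if data.classes is not None and post.eap["pi"].shape[0] == data.classes.n_classes:
            cs = data.classes
            G = cs.n_classes
            if G > 1:
                fam_err.setdefault("theta_mean", []).extend(
                    (np.atleast_2d(post.eap["mu_theta"])[1:].ravel()
                     - np.atleast_2d(np.asarray(cs.theta_mean, float).reshape(G, -1))[1:].ravel())
                )
                fam_err.setdefault("theta_var", []).extend(
                    (np.atleast_2d(post.eap["var_theta"])[1:].ravel()
                     - np.atleast_2d(np.asarray(cs.theta_var, float).reshape(G, -1))[1:].ravel())
                )
                fam_err.setdefault("omega_logmean", []).extend(
                    post.eap["mu_omega"][1:] - cs.omega_logmean[1:]
                )
                fam_err.setdefault("omega_logvar", []).extend(
                    post.eap["var_omega"][1:] - cs.omega_logvar[1:]
                )
        t_r, o_r, ccr, assigned, conf = _person_metrics(post, data)
        th_rmse.append(t_r)
        om_rmse.append(o_r)
        ccrs.append(ccr)
        confs.append(conf)
        per_rep.append({"theta_rmse": t_r, "omega_rmse": o_r, "ccr": ccr["overall"]})
    bias_d = {k: float(np.mean(v)) for k, v in fam_err.items()}
    rmse_d = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in fam_err.items()}
    keys = ccrs[0].keys()
    ccr_mean = {k: float(np.mean([c[k] for c in ccrs if k in c])) for k in keys}
    report = RecoveryReport(
        n_replications=R,
        bias=bias_d,
        rmse=rmse_d,
        ccr=ccr_mean,
        theta_rmse=float(np.mean(th_rmse)),
        omega_rmse=float(np.mean(om_rmse)),
        confusion=sum(confs),
        per_replication=per_rep,
    )
    report.validate()
    return report


@dataclass
class MisfitReport:
    """Consequences of fitting a reduced model to mixture data."""

    reduced_model: str
    ccr: Dict[str, float]
    theta_rmse: float
    omega_rmse: float
    assigned: np.ndarray
    scatter: Dict[str, np.ndarray]
    posterior: PosteriorSummary

    def scatter_to_csv(self, path) -> None:
        """Truth-vs-estimate pairs per misclassification type, one CSV."""
        import pandas as pd

        frames = []
        for key, pair in self.scatter.items():
            true_cls, assigned_cls = key.split("->")
            frames.append(pd.DataFrame({
                "true_class": int(true_cls),
                "assigned_class": int(assigned_cls),
                "theta_true": pair[0],
                "theta_estimate": pair[1],
            }))
        out = pd.concat(frames) if frames else pd.DataFrame(
            columns=["true_class", "assigned_class", "theta_true", "theta_estimate"]
        )
        out.to_csv(path, index=False)

    def shrinkage_slope(self, true_class: int, assigned_class: int) -> float:
        """OLS slope of trait estimate on truth for one misclassification cell.

        Slopes below 1 reproduce the EAP shrinkage pattern: high traits
        underestimated, low traits overestimated.
        """
        key = f"{true_class}->{assigned_class}"
        pair = self.scatter.get(key)
        if pair is None or pair.shape[1] < 3:
            raise ValueError(f"too few misclassified respondents in cell {key}")
        x, yv = pair
        x = x - x.mean()
        return float((x * (yv - yv.mean())).sum() / (x * x).sum())


def misfit_study(
    data: ResponseMatrix,
    reduced_model: str = "ers-gpcm",
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
) -> MisfitReport:
    """Fit a reduced (mixture-free) model to mixture-generated data.

    ``reduced_model`` is ``"ers-gpcm"`` (ERS kept, mixtures ignored; style
    classes recovered with the Wald-type +-1.96 test on the omega estimate)
    or ``"gpcm"`` (both ignored; everyone is called normal).  Returns CCR
    against the attached truth, person-parameter RMSEs, and truth-vs-estimate
    scatter pairs per misclassification type.
    """
    if data.persons is None:
        raise ValueError("misfit study requires attached generating truth")
    if reduced_model not in ("gpcm", "ers-gpcm"):
        raise ValueError("reduced model must be 'gpcm' or 'ers-gpcm'")
    spec = ModelSpec(family=reduced_model, n_classes=1, n_categories=data.n_categories)
    post = fit(data, spec, priors=priors, mcmc=mcmc)
    if reduced_model == "ers-gpcm":
        assigned = naive_ers_classify(post.omega_eap, np.maximum(post.omega_sd, 1e-8))
    else:
        assigned = np.zeros(data.n_respondents, dtype=int)
    truth_cls = data.true_classes()
    ccr = correct_classification_rate(assigned, truth_cls)
    theta_true = data.true_theta()
    omega_true = data.true_omega()
    theta_rmse = float(np.sqrt(np.mean((np.asarray(post.theta_eap) - theta_true) ** 2)))
    omega_rmse = float(np.sqrt(np.mean((post.omega_eap - omega_true) ** 2)))
    scatter: Dict[str, np.ndarray] = {}
    for g_true in np.unique(truth_cls):
        for g_hat in np.unique(assigned):
            if g_true == g_hat:
                continue
            mask = (truth_cls == g_true) & (assigned == g_hat)
            if mask.any():
                scatter[f"{g_true}->{g_hat}"] = np.vstack(
                    [theta_true[mask], np.asarray(post.theta_eap)[mask]]
                )
    return MisfitReport(
        reduced_model=reduced_model,
        ccr=ccr,
        theta_rmse=theta_rmse,
        omega_rmse=omega_rmse,
        assigned=assigned,
        scatter=scatter,
        posterior=post,
    )


def replicate_study(
    design: SimulationDesign,
    model_spec: Optional[ModelSpec] = None,
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    n_replications: int = 1,
    seed: int = 0,
) -> Tuple[RecoveryReport, List[PosteriorSummary], List[ResponseMatrix]]:
    """Repeat simulate -> fit -> evaluate and aggregate bias/RMSE/CCR.

    Each replication draws fresh items, persons and responses from ``design``
    (with a replication-specific sub-seed derived from ``seed``) and fits
    ``model_spec`` (default: the design's own generating mixture model).
    """
    import dataclasses

    if model_spec is None:
        family = "mix-ers-gpcm-cd" if design.mdp is not None else "mix-ers-gpcm"
        if design.n_classes == 1:
            family = "ers-gpcm-cd" if design.mdp is not None else "ers-gpcm"
        model_spec = ModelSpec(
            family=family,
            n_classes=design.n_classes,
            n_categories=design.n_categories,
            subscale_of_item=(
                np.arange(design.n_items) % design.n_subscales if design.n_subscales > 1 else None
            ),
        )
    mcmc = mcmc or McmcConfig()
    posts: List[PosteriorSummary] = []
    datas: List[ResponseMatrix] = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replications):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rep_design = dataclasses.replace(design, seed=rep_seed, tau_grid=design.tau_grid)
        data = simulate_dataset(rep_design)
        post = fit(data, model_spec, priors=priors, mcmc=dataclasses.replace(mcmc, seed=rep_seed))
        posts.append(post)
        datas.append(data)
    return recovery_report(posts, datas), posts, datas


def rank_order_change(reference, alternative) -> Dict[str, Union[np.ndarray, float]]:
    """Per-person |rank change| between two sets of trait estimates.

    Both vectors are ranked (ties broken by position, so the ordering is
    stable in the respondent index), and the absolute rank difference is
    reported per person together with its maximum and mean.
    """
    reference = np.asarray(reference, dtype=float)
    alternative = np.asarray(alternative, dtype=float)
    if reference.shape != alternative.shape:
        raise ValueError("estimate vectors must have equal length")
    r_ref = rankdata(reference, method="ordinal")
    r_alt = rankdata(alternative, method="ordinal")
    changes = np.abs(r_ref - r_alt).astype(int)
    return {"changes": changes, "max": int(changes.max()), "mean": float(changes.mean())}


def item_ers_elicitation(item_params: ItemParameters) -> Dict[str, np.ndarray]:
    """Per-item propensity to elicit extreme/mild response styles.

    The score is the item's discrimination on the omega dimension (``alpha2``,
    derived from the MDP split when not stored): a well-designed item has a
    low score.  Class-specific difficulty gaps |beta_normal - beta_g| are
    reported alongside for latent-DIF flagging.
    """
    score = item_params.effective_alpha2()
    out: Dict[str, np.ndarray] = {
        "score": np.asarray(score, dtype=float),
        "ranking": np.argsort(-np.asarray(score, dtype=float), kind="stable"),
    }
    for g in range(1, item_params.n_classes):
        out[f"beta_diff_class_{g}"] = np.abs(item_params.beta[0] - item_params.beta[g])
    return out
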