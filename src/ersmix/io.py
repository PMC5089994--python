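"""Plain-text formats: response CSV, truth JSON, and YAML/JSON configs.

Response files are UTF-8 comma-separated with a header
``respondent_id,item_1,...,item_I`` and categories coded ``1..J`` on disk;
in memory categories are ``0..J-1``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .models import ClassSpec, ItemParameters, PersonState
from .simulate import ResponseMatrix, SimulationDesign

__all__ = [
    "write_responses",
    "read_responses",
    "write_truth",
    "read_truth",
    "load_design",
    "dump_design",
    "load_config",
]


def write_responses(path: Union[str, Path], data: ResponseMatrix) -> None:
    """Write an N x I response matrix as CSV (categories re-coded 1..J)."""
    frame = pd.DataFrame(
        data.responses + 1,
        columns=[f"item_{i + 1}" for i in range(data.n_items)],
    )
    frame.insert(0, "respondent_id", np.arange(1, data.n_respondents + 1))
    frame.to_csv(path, index=False)


def read_responses(path: Union[str, Path], n_categories: Optional[int] = None) -> ResponseMatrix:
    """Read a response CSV; malformed rows are reported by row number."""
    frame = pd.read_csv(path)
    if "respondent_id" in frame.columns:
        frame = frame.drop(columns=["respondent_id"])
    numeric = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.where(~np.isfinite(numeric).all(axis=1) | (numeric != np.round(numeric)).any(axis=1))[0]
    if bad.size:
        raise ValueError(f"malformed response entries in row {bad[0] + 2} of {path}")
    values = numeric.astype(int)
    if n_categories is None:
        n_categories = int(values.max())
    if values.min() < 1 or values.max() > n_categories:
        row = int(np.where((values < 1) | (values > n_categories))[0][0])
        raise ValueError(f"category outside 1..{n_categories} in row {row + 2} of {path}")
    return ResponseMatrix(responses=values - 1, n_categories=n_categories)


def _maybe(x):
    return None if x is None else np.asarray(x).tolist()


def write_truth(path: Union[str, Path], data: ResponseMatrix) -> None:
    """Serialize the attached generating parameters to JSON."""
    if data.items is None or data.persons is None:
        raise ValueError("no attached truth to write")
    items = data.items
    doc = {
        "model": data.model,
        "n_categories": data.n_categories,
        "items": {
            "alpha1": items.alpha1.tolist(),
            "beta": items.beta.tolist(),
            "tau": items.tau.tolist(),
            "alpha2": _maybe(items.alpha2),
            "mdp": _maybe(items.mdp),
            "subscale_of_item": items.subscale_of_item.tolist(),
        },
        "persons": {
            "theta": [p.theta.tolist() for p in data.persons],
            "omega": [p.omega for p in data.persons],
            "class_label": [p.class_label for p in data.persons],
        },
    }
    if data.classes is not None:
        cs = data.classes
        doc["classes"] = {
            "mixing": cs.mixing.tolist(),
            "theta_mean": np.asarray(cs.theta_mean).tolist(),
            "theta_var": np.asarray(cs.theta_var).tolist(),
            "omega_logmean": cs.omega_logmean.tolist(),
            "omega_logvar": cs.omega_logvar.tolist(),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth(path: Union[str, Path]) -> ResponseMatrix:
    """Load generating truth (responses are not stored in truth files)."""
    doc = json.loads(Path(path).read_text())
    it = doc["items"]
    items = ItemParameters(
        alpha1=np.asarray(it["alpha1"]),
        beta=np.asarray(it["beta"]),
        tau=np.asarray(it["tau"]),
        alpha2=None if it.get("alpha2") is None else np.asarray(it["alpha2"]),
        mdp=None if it.get("mdp") is None else np.asarray(it["mdp"]),
        subscale_of_item=np.asarray(it["subscale_of_item"]),
    )
    pers = doc["persons"]
    persons = [
        PersonState(theta=np.asarray(t), omega=o, class_label=c)
        for t, o, c in zip(pers["theta"], pers["omega"], pers["class_label"])
    ]
    classes = None
    if "classes" in doc:
        c = doc["classes"]
        classes = ClassSpec(
            mixing=np.asarray(c["mixing"]),
            theta_mean=np.asarray(c["theta_mean"]),
            theta_var=np.asarray(c["theta_var"]),
            omega_logmean=np.asarray(c["omega_logmean"]),
            omega_logvar=np.asarray(c["omega_logvar"]),
        )
    n = len(persons)
    dummy = np.zeros((n, items.n_items), dtype=int)
    return ResponseMatrix(
        responses=dummy,
        n_categories=doc["n_categories"],
        items=items,
        persons=persons,
        classes=classes,
        model=doc.get("model"),
    )


def load_design(path: Union[str, Path]) -> SimulationDesign:
    """Read a simulation design from a YAML or JSON mapping."""
    raw = _load_mapping(path)
    known = SimulationDesign.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    if "class_proportions" in raw:
        raw["class_proportions"] = tuple(raw["class_proportions"])
    if "omega_dists" in raw:
        raw["omega_dists"] = tuple(tuple(x) for x in raw["omega_dists"])
    if "alpha1_dist" in raw:
        raw["alpha1_dist"] = tuple(raw["alpha1_dist"])
    if "beta_range" in raw:
        raw["beta_range"] = tuple(raw["beta_range"])
    return SimulationDesign(**raw)


def dump_design(path: Union[str, Path], design: SimulationDesign) -> None:
    doc = asdict(design)
    doc["tau_grid"] = np.asarray(design.tau_grid).tolist()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _load_mapping(path: Union[str, Path]) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return doc


def load_config(path: Union[str, Path]) -> dict:
    """Generic YAML/JSON mapping loader for CLI run configs."""
    return _load_mapping(path)
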