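"""Detection-probability models and the Huggins conditional likelihood.

The estimator is a closed-population capture-recapture model with three
occasions per group: a "radio observer" whose detection probability is fixed
at 1 for telemetry-collared groups and 0 for uncollared groups, and two
visual observers whose detection probabilities follow a logit-linear model.
Uncollared groups enter the likelihood conditionally on being seen at least
once (Huggins conditional likelihood); collared groups enter unconditionally
— the radio occasion guarantees their inclusion, so a collared group missed
by both observers still contributes a (0,0) history and informs residual
heterogeneity.

Residual heterogeneity (group-to-group variation in sightability beyond
covariates) is absorbed by three surrogate parameterizations:

1. a *type* effect — an additive logit shift for collared groups;
2. a *recapture* (behavioural-response) effect — observer 2's detection
   probability differs when observer 1 already detected the group, which in
   simultaneous double-observer data soaks up the positive detection
   dependence heterogeneity induces;
3. both combined.

The radio occasion never triggers the recapture effect: a telemetry
"detection" is not a sighting event and cannot induce observer behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .survey_data import SurveyDataset, validate_dataset

__all__ = [
    "DetectionModelSpec",
    "DesignMatrices",
    "build_design",
    "inverse_link",
    "history_probability",
    "negative_log_likelihood",
    "nll_and_gradient",
    "predict_detection",
]

#: covariates a model may use, in canonical order
VALID_COVARIATES = ("ln_size", "forest", "pct_conceal", "pct_snow", "moving")

#: record field backing each covariate
_COVARIATE_FIELDS = {
    "ln_size": "size_best",
    "forest": "forest",
    "pct_conceal": "pct_conceal",
    "pct_snow": "pct_snow",
    "moving": "moving",
}

#: display name used in auto-generated model labels (MARK-style)
_COVARIATE_LABELS = {
    "ln_size": "groupsize",
    "forest": "forest",
    "pct_conceal": "conceal",
    "pct_snow": "snow",
    "moving": "moving",
}


@dataclass(frozen=True)
class DetectionModelSpec:
    """Structure of one detection model.

    Parameters
    ----------
    observer_effect
        Separate logit intercepts for observer 1 and observer 2 (else one
        shared intercept).
    type_effect
        Additive logit term for collared groups (heterogeneity surrogate 1).
    recapture_effect
        Additive logit term on observer 2 when observer 1 detected the group
        (heterogeneity surrogate 2; both flags on = combined model 3).
    covariates
        Subset of ``("ln_size", "forest", "pct_conceal", "pct_snow",
        "moving")`` entering additively on the logit scale, shared across
        observers.
    """

    observer_effect: bool = True
    type_effect: bool = False
    recapture_effect: bool = False
    covariates: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        covs = tuple(self.covariates)
        unknown = [c for c in covs if c not in VALID_COVARIATES]
        if unknown:
            raise ValueError(f"unknown covariate(s): {unknown}; valid: {VALID_COVARIATES}")
        if len(set(covs)) != len(covs):
            raise ValueError("duplicate covariates in spec")
        covs = tuple(c for c in VALID_COVARIATES if c in covs)
        object.__setattr__(self, "covariates", covs)
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        parts = ["observer"]
        if self.type_effect:
            parts.append("type")
        if self.recapture_effect:
            parts.append("recapture")
        parts.extend(_COVARIATE_LABELS[c] for c in self.covariates)
        return " + ".join(parts)

    def coef_names(self) -> list[str]:
        names = ["b_obs1", "b_obs2"] if self.observer_effect else ["b0"]
        if self.type_effect:
            names.append("b_type")
        if self.recapture_effect:
            names.append("b_recap")
        names.extend(f"b_{c}" for c in self.covariates)
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.coef_names())

    def required_record_fields(self) -> list[str]:
        """Record fields that must be non-missing for every group."""
        return [_COVARIATE_FIELDS[c] for c in self.covariates]

    def to_dict(self) -> dict:
        return {
            "observer_effect": self.observer_effect,
            "type_effect": self.type_effect,
            "recapture_effect": self.recapture_effect,
            "covariates": list(self.covariates),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DetectionModelSpec":
        return cls(
            observer_effect=bool(d.get("observer_effect", True)),
            type_effect=bool(d.get("type_effect", False)),
            recapture_effect=bool(d.get("recapture_effect", False)),
            covariates=tuple(d.get("covariates", ())),
            label=str(d.get("label", "")),
        )


@dataclass
class DesignMatrices:
    """Linear-predictor design for one (dataset, spec) pair.

    ``X1`` drives observer 1, ``X2_init`` observer 2 when observer 1 missed
    the group, ``X2_recap`` observer 2 after an observer-1 detection (equal
    to ``X2_init`` unless the spec has a recapture effect).  The radio
    occasion contributes no rows — its probability is fixed by design.
    """

    spec: DetectionModelSpec
    coef_names: list[str]
    X1: np.ndarray
    X2_init: np.ndarray
    X2_recap: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    collared: np.ndarray  # bool
    size_best: np.ndarray
    group_ids: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long view: one row per (group, observer) with design columns."""
        rows = []
        for obs, X in ((1, self.X1), (2, self.X2_init)):
            df = pd.DataFrame(X, columns=self.coef_names)
            df.insert(0, "observer", obs)
            df.insert(0, "group_id", self.group_ids)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def linear_predictors(self, beta: np.ndarray):
        return self.X1 @ beta, self.X2_init @ beta, self.X2_recap @ beta


def build_design(dataset: SurveyDataset, spec: DetectionModelSpec) -> DesignMatrices:
    """Construct design matrices for the detection model on a dataset."""
    issues = validate_dataset(dataset, spec)
    if issues:
        raise ValueError("invalid dataset for spec: " + "; ".join(issues))
    n = dataset.n_groups
    names = spec.coef_names()
    k = len(names)
    X1 = np.zeros((n, k))
    X2i = np.zeros((n, k))
    col = {name: j for j, name in enumerate(names)}

    if spec.observer_effect:
        X1[:, col["b_obs1"]] = 1.0
        X2i[:, col["b_obs2"]] = 1.0
    else:
        X1[:, col["b0"]] = 1.0
        X2i[:, col["b0"]] = 1.0

    collared = np.array([bool(r.collared) for r in dataset.records])
    if spec.type_effect:
        X1[:, col["b_type"]] = collared
        X2i[:, col["b_type"]] = collared

    for c in spec.covariates:
        fname = _COVARIATE_FIELDS[c]
        vals = np.array([float(getattr(r, fname)) for r in dataset.records])
        if c == "ln_size":
            if np.any(vals < 1):
                raise ValueError("size_best < 1 with ln_size requested")
            vals = np.log(vals)
        X1[:, col[f"b_{c}"]] = vals
        X2i[:, col[f"b_{c}"]] = vals

    X2r = X2i.copy()
    if spec.recapture_effect:
        X2r[:, col["b_recap"]] = 1.0

    return DesignMatrices(
        spec=spec,
        coef_names=names,
        X1=X1,
        X2_init=X2i,
        X2_recap=X2r,
        y1=np.array([r.detected_obs1 for r in dataset.records], dtype=float),
        y2=np.array([r.detected_obs2 for r in dataset.records], dtype=float),
        collared=collared,
        size_best=np.array([float(r.size_best) for r in dataset.records]),
        group_ids=[r.group_id for r in dataset.records],
    )


def inverse_link(eta):
    """Logistic inverse link mapping a linear predictor to a probability."""
    return expit(eta)


def history_probability(
    p1: float,
    p2_init: float,
    p2_recap: float,
    history: tuple[int, int],
    collared: bool,
) -> float:
    """Probability of one group's visual capture history.

    Observer 2's probability is ``p2_recap`` when observer 1 detected the
    group, else ``p2_init``.  For uncollared groups the probability is
    conditioned on detection by at least one observer (divide by
    ``p* = 1 - (1-p1)(1-p2_init)``); collared groups return the
    unconditional probability, so the all-zero history is admissible with
    probability ``(1-p1)(1-p2_init)``.
    """
    for name, p in (("p1", p1), ("p2_init", p2_init), ("p2_recap", p2_recap)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    y1, y2 = history
    if y1 not in (0, 1) or y2 not in (0, 1):
        raise ValueError(f"history entries must be 0/1, got {history}")
    if not collared and y1 == 0 and y2 == 0:
        raise ValueError("uncollared group with all-zero history is unobservable")
    p2 = p2_recap if y1 == 1 else p2_init
    prob = (p1 if y1 else 1.0 - p1) * (p2 if y2 else 1.0 - p2)
    if not collared:
        pstar = 1.0 - (1.0 - p1) * (1.0 - p2_init)
        prob /= pstar
    return prob


def _eta_terms(beta: np.ndarray, design: DesignMatrices):
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite coefficient vector")
    return design.linear_predictors(beta)


def negative_log_likelihood(beta: np.ndarray, design: DesignMatrices) -> float:
    """Huggins conditional negative log-likelihood, summed over groups."""
    return nll_and_gradient(beta, design)[0]


def nll_and_gradient(beta: np.ndarray, design: DesignMatrices) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the negative log-likelihood.

    Written in numerically stable form via ``log_expit``; the conditioning
    term uses ``log(-expm1(.))`` so that small detection probabilities do
    not lose precision.
    """
    eta1, eta2i, eta2r = _eta_terms(beta, design)
    y1, y2 = design.y1, design.y2
    coll = design.collared
    seen1 = y1 == 1

    lp1 = y1 * log_expit(eta1) + (1 - y1) * log_expit(-eta1)
    eta2 = np.where(seen1, eta2r, eta2i)
    lp2 = y2 * log_expit(eta2) + (1 - y2) * log_expit(-eta2)

    # log q = log[(1-p1)(1-p2_init)]; p* = 1 - q
    log_q = log_expit(-eta1) + log_expit(-eta2i)
    with np.errstate(divide="ignore"):
        log_pstar = np.log(-np.expm1(log_q))
    ll = lp1 + lp2 - np.where(coll, 0.0, log_pstar)
    nll = -float(np.sum(ll))

    p1 = expit(eta1)
    p2i = expit(eta2i)
    p2r = expit(eta2r)
    pstar = np.maximum(-np.expm1(log_q), 1e-300)
    uncoll = ~coll
    a1 = (y1 - p1) - uncoll * (p1 * (1 - p1) * (1 - p2i) / pstar)
    a2i = (1 - y1) * (y2 - p2i) - uncoll * (p2i * (1 - p2i) * (1 - p1) / pstar)
    a2r = y1 * (y2 - p2r)
    grad = -(design.X1.T @ a1 + design.X2_init.T @ a2i + design.X2_recap.T @ a2r)
    return nll, grad


def group_probabilities(beta: np.ndarray, design: DesignMatrices):
    """Per-group detection probabilities (p1, p2_init, p2_recap) at beta."""
    eta1, eta2i, eta2r = _eta_terms(beta, design)
    return expit(eta1), expit(eta2i), expit(eta2r)


def predict_detection(
    beta: Mapping[str, float],
    spec: DetectionModelSpec,
    sizes: Sequence[float] | np.ndarray = (),
    forest: int | Sequence[int] = 0,
    collared: bool = False,
    **fixed: float,
) -> pd.DataFrame:
    """Predicted per-observer detection probability over a covariate grid.

    Produces the data behind detection-vs-group-size curves: one row per
    grid point with initial (non-recapture) detection probabilities for
    each observer.  Covariates not on the grid are held at ``fixed`` values
    (default 0).
    """
    sizes = np.atleast_1d(np.asarray(sizes, dtype=float)) if len(np.atleast_1d(sizes)) else np.array([1.0])
    if np.any(sizes < 1):
        raise ValueError("group sizes must be >= 1")
    forest_arr = np.broadcast_to(np.atleast_1d(np.asarray(forest, dtype=float)), sizes.shape).copy() \
        if np.ndim(forest) else np.full_like(sizes, float(forest))

    def coef(name):
        return float(beta.get(name, 0.0))

    if spec.observer_effect:
        eta1 = np.full_like(sizes, coef("b_obs1"))
        eta2 = np.full_like(sizes, coef("b_obs2"))
    else:
        eta1 = np.full_like(sizes, coef("b0"))
        eta2 = eta1.copy()
    shared = np.zeros_like(sizes)
    if spec.type_effect and collared:
        shared += coef("b_type")
    for c in spec.covariates:
        if c == "ln_size":
            shared += coef("b_ln_size") * np.log(sizes)
        elif c == "forest":
            shared += coef("b_forest") * forest_arr
        else:
            shared += coef(f"b_{c}") * float(fixed.get(c, 0.0))
    eta1 = eta1 + shared
    eta2 = eta2 + shared
    return pd.DataFrame(
        {
            "size": sizes,
            "forest": forest_arr.astype(int),
            "p_obs1": expit(eta1),
            "p_obs2": expit(eta2),
        }
    )
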