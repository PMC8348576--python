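"""Maximum-likelihood fitting, AICc, model ranking and Akaike weights.

The central object is :class:`HugginsDetectionModel`, a scikit-learn style
estimator: construct with the model structure and fitting options, ``fit``
on a survey dataset, then read fitted attributes (``coef_``, ``vcov_``,
``aicc_``, ...) or call ``predict_detection``.  The module-level
``fit_model`` / ``fit_model_set`` functions are thin wrappers for callers
who prefer the functional interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .detection import (
    DetectionModelSpec,
    DesignMatrices,
    build_design,
    group_probabilities,
    nll_and_gradient,
    predict_detection,
)
from .survey_data import SurveyDataset

__all__ = [
    "FitConfig",
    "FittedModel",
    "ModelSet",
    "HugginsDetectionModel",
    "IdentifiabilityError",
    "ConvergenceError",
    "fit_model",
    "fit_model_set",
    "compute_aicc",
    "akaike_weights",
]

logger = logging.getLogger(__name__)

#: detection probabilities within this distance of 0/1 flag a boundary fit
BOUNDARY_TOL = 1e-6


class IdentifiabilityError(ValueError):
    """A model term has no information in the data (e.g. no collared groups)."""


class ConvergenceError(RuntimeError):
    """The optimizer failed from every start."""


@dataclass(frozen=True)
class FitConfig:
    """Options controlling one maximum-likelihood fit.

    ``n_eff_rule`` selects the effective sample size used by AICc:
    ``"groups"`` (default) counts groups contributing likelihood terms;
    ``"detections"`` counts detection events (observer sightings plus radio
    detections of collared groups).  Reports print the rule in force.
    """

    seed: int = 0
    n_starts: int = 5
    tol: float = 1e-8
    n_eff_rule: str = "groups"
    include_boundary: bool = False
    start_scale: float = 0.5
    max_iter: int = 500

    def __post_init__(self):
        if self.n_eff_rule not in ("groups", "detections"):
            raise ValueError("n_eff_rule must be 'groups' or 'detections'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def compute_aicc(loglik: float, k: int, n_eff: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``-2 logLik + 2K + 2K(K+1)/(n_eff - K - 1)``; requires ``n_eff > K + 1``.
    """
    if n_eff <= k + 1:
        raise ValueError(f"AICc undefined: n_eff={n_eff} must exceed K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2), Δ relative to the best."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc sequence")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AICc value")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


@dataclass
class FittedModel:
    """A fitted detection model: estimates, covariance and information criteria."""

    spec: DetectionModelSpec
    beta: dict[str, float]
    vcov: np.ndarray | None
    loglik: float
    k: int
    n_eff: int
    n_eff_rule: str
    aicc: float
    converged: bool
    boundary: bool

    @property
    def label(self) -> str:
        return self.spec.label

    def beta_array(self) -> np.ndarray:
        return np.array([self.beta[n] for n in self.spec.coef_names()])

    def se(self) -> dict[str, float] | None:
        """Wald standard errors, or None when the covariance is unavailable."""
        if self.vcov is None:
            return None
        d = np.sqrt(np.maximum(np.diag(self.vcov), 0.0))
        return dict(zip(self.spec.coef_names(), d))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "beta": self.beta,
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "n_eff": self.n_eff,
            "n_eff_rule": self.n_eff_rule,
            "aicc": self.aicc,
            "converged": self.converged,
            "boundary": self.boundary,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        vcov = d.get("vcov")
        return cls(
            spec=DetectionModelSpec.from_dict(d["spec"]),
            beta=dict(d["beta"]),
            vcov=None if vcov is None else np.asarray(vcov, dtype=float),
            loglik=float(d["loglik"]),
            k=int(d["k"]),
            n_eff=int(d["n_eff"]),
            n_eff_rule=str(d.get("n_eff_rule", "groups")),
            aicc=float(d["aicc"]),
            converged=bool(d["converged"]),
            boundary=bool(d["boundary"]),
        )


@dataclass
class ModelSet:
    """AICc-ranked models fitted to one dataset, with Akaike weights."""

    models: list[FittedModel]
    delta_aicc: np.ndarray
    weights: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Model-selection table (Model, K, AICc, ΔAICc, w_i)."""
        return pd.DataFrame(
            {
                "Model": [m.label for m in self.models],
                "K": [m.k for m in self.models],
                "AICc": [m.aicc for m in self.models],
                "ΔAICc": self.delta_aicc,
                "w_i": self.weights,
            }
        )

    def to_dict(self) -> dict:
        return {
            "models": [m.to_dict() for m in self.models],
            "delta_aicc": self.delta_aicc.tolist(),
            "weights": self.weights.tolist(),
            "excluded": [list(e) for e in self.excluded],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSet":
        return cls(
            models=[FittedModel.from_dict(m) for m in d["models"]],
            delta_aicc=np.asarray(d["delta_aicc"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            excluded=[tuple(e) for e in d.get("excluded", [])],
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ModelSet":
        return cls.from_dict(json.loads(s))


def _as_dataset(X) -> SurveyDataset:
    if isinstance(X, SurveyDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return SurveyDataset.from_frame(X)
    raise TypeError(f"expected SurveyDataset or DataFrame, got {type(X).__name__}")


def _check_identifiable(design: DesignMatrices, spec: DetectionModelSpec) -> None:
    n = design.n_groups
    if n == 0:
        raise IdentifiabilityError("empty dataset")
    n_coll = int(design.collared.sum())
    if spec.type_effect and (n_coll == 0 or n_coll == n):
        raise IdentifiabilityError(
            f"type effect unidentifiable: {n_coll} of {n} groups collared"
        )
    if spec.recapture_effect and not np.any(design.y1 == 1):
        raise IdentifiabilityError("recapture effect unidentifiable: no observer-1 detections")
    for c in spec.covariates:
        col = spec.coef_names().index(f"b_{c}")
        if np.ptp(design.X1[:, col]) == 0:
            raise IdentifiabilityError(f"covariate {c!r} has no variation across groups")


def _hessian(beta: np.ndarray, design: DesignMatrices) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    k = beta.size
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(beta[j]))
        bp = beta.copy()
        bp[j] += h
        bm = beta.copy()
        bm[j] -= h
        gp = nll_and_gradient(bp, design)[1]
        gm = nll_and_gradient(bm, design)[1]
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


class HugginsDetectionModel(BaseEstimator):
    """Huggins closed-capture detection model for double-observer surveys.

    Scikit-learn style estimator.  ``X`` for :meth:`fit` is a
    :class:`~dosabund.survey_data.SurveyDataset` or an equivalent
    ``DataFrame``; there is no ``y`` (the capture histories live in ``X``).

    Parameters mirror :class:`~dosabund.detection.DetectionModelSpec` plus
    the fitting options of :class:`FitConfig`.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray of shape (K,)
        Maximum conditional-likelihood estimates on the logit scale.
    coef_names_ : list of str
    vcov_ : ndarray or None
        Inverse observed information; None when the Hessian is singular.
    loglik_, aicc_, k_, n_eff_ : floats/ints
    converged_, boundary_ : bool
        ``boundary_`` flags any fitted detection probability within 1e-6
        of 0 or 1 (degenerate variance).
    """

    def __init__(
        self,
        observer_effect: bool = True,
        type_effect: bool = False,
        recapture_effect: bool = False,
        covariates: tuple[str, ...] = (),
        label: str = "",
        seed: int = 0,
        n_starts: int = 5,
        tol: float = 1e-8,
        n_eff_rule: str = "groups",
        start_scale: float = 0.5,
        max_iter: int = 500,
    ):
        self.observer_effect = observer_effect
        self.type_effect = type_effect
        self.recapture_effect = recapture_effect
        self.covariates = covariates
        self.label = label
        self.seed = seed
        self.n_starts = n_starts
        self.tol = tol
        self.n_eff_rule = n_eff_rule
        self.start_scale = start_scale
        self.max_iter = max_iter

    @classmethod
    def from_spec(cls, spec: DetectionModelSpec, config: FitConfig | None = None
                  ) -> "HugginsDetectionModel":
        config = config or FitConfig()
        return cls(
            observer_effect=spec.observer_effect,
            type_effect=spec.type_effect,
            recapture_effect=spec.recapture_effect,
            covariates=spec.covariates,
            label=spec.label,
            seed=config.seed,
            n_starts=config.n_starts,
            tol=config.tol,
            n_eff_rule=config.n_eff_rule,
            start_scale=config.start_scale,
            max_iter=config.max_iter,
        )

    def _spec(self) -> DetectionModelSpec:
        return DetectionModelSpec(
            observer_effect=self.observer_effect,
            type_effect=self.type_effect,
            recapture_effect=self.recapture_effect,
            covariates=tuple(self.covariates),
            label=self.label,
        )

    def fit(self, X, y=None) -> "HugginsDetectionModel":
        dataset = _as_dataset(X)
        spec = self._spec()
        design = build_design(dataset, spec)
        _check_identifiable(design, spec)
        k = len(design.coef_names)

        rng = np.random.default_rng(self.seed)
        starts = [np.zeros(k)]
        starts += [rng.normal(0.0, self.start_scale, size=k) for _ in range(self.n_starts - 1)]

        best = None
        for x0 in starts:
            res = minimize(
                nll_and_gradient,
                x0,
                args=(design,),
                jac=True,
                method="BFGS",
                options={"gtol": self.tol, "maxiter": self.max_iter},
            )
            gnorm = float(np.max(np.abs(res.jac)))
            ok = res.success or gnorm < 1e-6
            if best is None or (ok, -res.fun) > (best[1], -best[0].fun):
                best = (res, ok)
        res, converged = best

        beta_hat = res.x
        p1, p2i, p2r = group_probabilities(beta_hat, design)
        probs = np.concatenate([p1, p2i, p2r])
        boundary = bool(np.any(probs < BOUNDARY_TOL) | np.any(probs > 1 - BOUNDARY_TOL))

        vcov = None
        if converged:
            H = _hessian(beta_hat, design)
            if np.all(np.isfinite(H)):
                try:
                    if np.linalg.cond(H) < 1e12:
                        vcov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    vcov = None
        if vcov is not None and not np.all(np.isfinite(vcov)):
            vcov = None

        loglik = -float(res.fun)
        if self.n_eff_rule == "groups":
            n_eff = design.n_groups
        else:
            n_eff = int(design.y1.sum() + design.y2.sum() + design.collared.sum())

        self.design_ = design
        self.spec_ = spec
        self.coef_ = beta_hat
        self.coef_names_ = list(design.coef_names)
        self.vcov_ = vcov
        self.loglik_ = loglik
        self.k_ = k
        self.n_eff_ = n_eff
        self.n_groups_ = design.n_groups
        self.aicc_ = compute_aicc(loglik, k, n_eff)
        self.converged_ = bool(converged)
        self.boundary_ = boundary
        return self

    def predict_detection(self, sizes=(), forest=0, **fixed) -> pd.DataFrame:
        """Detection-probability curves over a covariate grid (see
        :func:`dosabund.detection.predict_detection`)."""
        self._check_fitted()
        beta = dict(zip(self.coef_names_, self.coef_))
        return predict_detection(beta, self.spec_, sizes=sizes, forest=forest, **fixed)

    def fitted_model(self) -> FittedModel:
        """Serializable summary of the fit."""
        self._check_fitted()
        return FittedModel(
            spec=self.spec_,
            beta=dict(zip(self.coef_names_, map(float, self.coef_))),
            vcov=self.vcov_,
            loglik=self.loglik_,
            k=self.k_,
            n_eff=self.n_eff_,
            n_eff_rule=self.n_eff_rule,
            aicc=self.aicc_,
            converged=self.converged_,
            boundary=self.boundary_,
        )

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted; call fit() first")


def fit_model(
    dataset: SurveyDataset | pd.DataFrame,
    spec: DetectionModelSpec,
    config: FitConfig | None = None,
) -> FittedModel:
    """Fit one detection model by maximum conditional likelihood."""
    est = HugginsDetectionModel.from_spec(spec, config)
    est.fit(dataset)
    return est.fitted_model()


def fit_model_set(
    dataset: SurveyDataset | pd.DataFrame,
    specs: Sequence[DetectionModelSpec],
    config: FitConfig | None = None,
) -> ModelSet:
    """Fit a candidate set on one dataset and rank by AICc.

    Models that are unidentifiable, fail to converge, or sit on the
    probability boundary (unless ``include_boundary``) are excluded from
    ranking and weights, with a logged warning; they are listed in
    ``ModelSet.excluded`` with the reason.
    """
    if not specs:
        raise ValueError("need at least one model spec")
    config = config or FitConfig()
    fitted: list[FittedModel] = []
    excluded: list[tuple[str, str]] = []
    for spec in specs:
        try:
            fm = fit_model(dataset, spec, config)
        except (IdentifiabilityError, ValueError) as exc:
            logger.warning("model %r excluded: %s", spec.label, exc)
            excluded.append((spec.label, str(exc)))
            continue
        if not fm.converged:
            logger.warning("model %r excluded: did not converge", spec.label)
            excluded.append((spec.label, "did not converge"))
        elif fm.boundary and not config.include_boundary:
            logger.warning("model %r excluded: boundary estimate", spec.label)
            excluded.append((spec.label, "boundary estimate (fitted p at 0 or 1)"))
        else:
            fitted.append(fm)
    if not fitted:
        raise ConvergenceError("all candidate models failed to converge or were excluded")
    fitted.sort(key=lambda m: (m.aicc, m.k, m.label))
    aiccs = np.array([m.aicc for m in fitted])
    return ModelSet(
        models=fitted,
        delta_aicc=aiccs - aiccs.min(),
        weights=akaike_weights(aiccs),
        excluded=excluded,
    )
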