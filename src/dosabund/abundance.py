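"""Horvitz-Thompson abundance, lognormal intervals, and model averaging.

Abundance follows from a fitted detection model by inverse-probability
weighting: each observed group contributes its (photo-confirmed) size
divided by the probability that the group entered the sample at all.  For
uncollared groups that inclusion probability is ``p* = 1 - (1-p1)(1-p2)``;
collared groups are included with certainty through the radio occasion, so
they contribute their size exactly.  The estimate can therefore never fall
below M, the number of individuals known present.

Uncertainty combines the binomial variation of inclusion with the sampling
variance of the detection coefficients (delta method), and the confidence
interval is lognormal on ``f0 = N_hat - M`` so the lower limit never drops
below the known minimum count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .detection import build_design
from .estimation import FittedModel, ModelSet
from .survey_data import SurveyDataset

__all__ = [
    "AbundanceEstimate",
    "AveragedEstimate",
    "inclusion_probability",
    "horvitz_thompson",
    "lognormal_interval",
    "model_average",
]

#: inclusion probabilities below this abort estimation (the HT term explodes)
P_STAR_FLOOR = 1e-6


@dataclass
class AbundanceEstimate:
    """Horvitz-Thompson abundance with SE and lognormal confidence interval."""

    N_hat: float
    SE: float
    M: int
    ci_low: float
    ci_high: float
    level: float = 0.95
    survey_label: str = ""
    model_label: str = ""

    @property
    def variance(self) -> float:
        return self.SE**2

    def to_dict(self) -> dict:
        return {
            "N_hat": self.N_hat,
            "SE": self.SE,
            "M": self.M,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "survey_label": self.survey_label,
            "model_label": self.model_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AbundanceEstimate":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class AveragedEstimate:
    """AICc-weighted model-averaged abundance with unconditional SE."""

    estimates: list[AbundanceEstimate]
    weights: np.ndarray
    N_bar: float
    SE_unconditional: float
    M: int
    ci_low: float
    ci_high: float
    level: float = 0.95
    survey_label: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": [e.to_dict() for e in self.estimates],
            "weights": self.weights.tolist(),
            "N_bar": self.N_bar,
            "SE_unconditional": self.SE_unconditional,
            "M": self.M,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "survey_label": self.survey_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AveragedEstimate":
        return cls(
            estimates=[AbundanceEstimate.from_dict(e) for e in d["estimates"]],
            weights=np.asarray(d["weights"], dtype=float),
            N_bar=float(d["N_bar"]),
            SE_unconditional=float(d["SE_unconditional"]),
            M=int(d["M"]),
            ci_low=float(d["ci_low"]),
            ci_high=float(d["ci_high"]),
            level=float(d.get("level", 0.95)),
            survey_label=str(d.get("survey_label", "")),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def inclusion_probability(p1, p2_init, collared):
    """Probability a group enters the sample.

    Collared groups are detected with certainty by the radio occasion
    (probability exactly 1); uncollared groups must be seen by at least one
    visual observer: ``p* = 1 - (1-p1)(1-p2_init)``.  Vectorized.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2_init, dtype=float)
    coll = np.asarray(collared, dtype=bool)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pstar = 1.0 - (1.0 - p1) * (1.0 - p2)
    out = np.where(coll, 1.0, pstar)
    return out if out.ndim else float(out)


def _n_hat(beta: np.ndarray, design) -> float:
    eta1 = design.X1 @ beta
    eta2 = design.X2_init @ beta
    pstar = np.where(design.collared, 1.0, 1.0 - (1.0 - expit(eta1)) * (1.0 - expit(eta2)))
    return float(np.sum(design.size_best / pstar))


def horvitz_thompson(
    fitted: FittedModel,
    dataset: SurveyDataset,
    level: float = 0.95,
) -> AbundanceEstimate:
    """Horvitz-Thompson abundance under one fitted detection model.

    ``N_hat = Σ_i s_i / p*_i`` with group-specific inclusion probabilities.
    Variance is the usual two-part form: binomial inclusion variance
    ``Σ s_i² (1-p*_i)/p*_i²`` (zero for collared groups) plus the
    delta-method term ``Gᵀ V G`` with ``G`` the gradient of ``N_hat`` with
    respect to the detection coefficients.
    """
    if not fitted.converged:
        raise ValueError(f"model {fitted.label!r} did not converge")
    design = build_design(dataset, fitted.spec)
    beta = fitted.beta_array()

    eta1 = design.X1 @ beta
    eta2 = design.X2_init @ beta
    p1 = expit(eta1)
    p2 = expit(eta2)
    pstar = np.asarray(inclusion_probability(p1, p2, design.collared))
    low = pstar < P_STAR_FLOOR
    if np.any(low):
        bad = [g for g, b in zip(design.group_ids, low) if b]
        raise ValueError(
            f"inclusion probability below {P_STAR_FLOOR:g} for group(s) {bad}; "
            "the Horvitz-Thompson estimate would be unstable"
        )

    sizes = design.size_best
    n_hat = float(np.sum(sizes / pstar))
    var_inclusion = float(
        np.sum(np.where(design.collared, 0.0, sizes**2 * (1.0 - pstar) / pstar**2))
    )

    if fitted.vcov is None:
        raise ValueError(
            f"model {fitted.label!r} has no coefficient covariance; cannot propagate "
            "detection uncertainty"
        )
    k = beta.size
    G = np.empty(k)
    for j in range(k):
        h = 1e-6 * max(1.0, abs(beta[j]))
        bp = beta.copy()
        bp[j] += h
        bm = beta.copy()
        bm[j] -= h
        G[j] = (_n_hat(bp, design) - _n_hat(bm, design)) / (2 * h)
    var_coef = float(G @ fitted.vcov @ G)
    se = float(np.sqrt(max(var_inclusion + max(var_coef, 0.0), 0.0)))

    m = dataset.total_size_best
    lo, hi = lognormal_interval(n_hat, se, m, level=level)
    return AbundanceEstimate(
        N_hat=n_hat,
        SE=se,
        M=m,
        ci_low=lo,
        ci_high=hi,
        level=level,
        survey_label=dataset.survey_label,
        model_label=fitted.label,
    )


def lognormal_interval(n_hat: float, se: float, m: int, level: float = 0.95
                       ) -> tuple[float, float]:
    """Lognormal confidence interval on the unobserved component f0 = N_hat - M.

    ``C = exp(z sqrt(ln(1 + (SE/f0)²)))``; limits ``M + f0/C`` and
    ``M + f0·C``.  Degenerate cases (``f0 <= 0`` or ``SE = 0``) collapse to
    the point estimate.  Guarantees the lower limit never falls below the
    minimum known count M.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if se < 0:
        raise ValueError("SE must be nonnegative")
    if n_hat < m:
        raise ValueError(f"N_hat={n_hat} below minimum known count M={m}")
    f0 = n_hat - m
    if f0 <= 0 or se == 0:
        return (n_hat, n_hat)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    c = np.exp(z * np.sqrt(np.log1p((se / f0) ** 2)))
    return (m + f0 / c, m + f0 * c)


def model_average(
    model_set: ModelSet,
    estimates: Sequence[AbundanceEstimate],
    level: float = 0.95,
) -> AveragedEstimate:
    """AICc-weighted average of per-model abundance estimates.

    ``N̄ = Σ w_k N̂_k`` with the unconditional standard error
    ``Σ w_k sqrt(var_k + (N̂_k - N̄)²)``, which inflates the within-model
    SEs by the between-model spread.  The interval is lognormal on
    ``f0 = N̄ - M`` with the shared minimum count M.
    """
    estimates = list(estimates)
    if len(estimates) != len(model_set.models):
        raise ValueError(
            f"{len(estimates)} estimates for {len(model_set.models)} weighted models"
        )
    for est, m in zip(estimates, model_set.models):
        if est.model_label != m.label:
            raise ValueError(
                f"estimate order mismatch: {est.model_label!r} vs model {m.label!r}"
            )
    ms = {e.M for e in estimates}
    if len(ms) != 1:
        raise ValueError(f"estimates disagree on the minimum count M: {sorted(ms)}")
    m_count = ms.pop()

    w = np.asarray(model_set.weights, dtype=float)
    n_hats = np.array([e.N_hat for e in estimates])
    n_bar = float(w @ n_hats)
    se_unc = float(np.sum(w * np.sqrt(np.array([e.variance for e in estimates])
                                      + (n_hats - n_bar) ** 2)))
    lo, hi = lognormal_interval(n_bar, se_unc, m_count, level=level)
    return AveragedEstimate(
        estimates=estimates,
        weights=w,
        N_bar=n_bar,
        SE_unconditional=se_unc,
        M=m_count,
        ci_low=lo,
        ci_high=hi,
        level=level,
        survey_label=estimates[0].survey_label,
    )


def estimate_abundance(
    model_set: ModelSet,
    dataset: SurveyDataset,
    level: float = 0.95,
) -> tuple[list[AbundanceEstimate], AveragedEstimate]:
    """Per-model Horvitz-Thompson estimates plus their model average."""
    ests = [horvitz_thompson(m, dataset, level=level) for m in model_set.models]
    return ests, model_average(model_set, ests, level=level)
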