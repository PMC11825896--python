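"""Counterfactual effect estimation from a fitted latent-health model.

The average treatment effect of admission on an outcome is the mean, over
visits, of the difference between the predicted outcome probability under
hypothetical admission and hypothetical discharge, holding every other
variable (and hence the visit's posterior over the latent state) at its
observed value:

    rd = (1/n) sum_i [ p_k(gamma_i, A=1) - p_k(gamma_i, A=0) ]

with p_k(gamma, a) = gamma * p_k(H=1, a) + (1 - gamma) * p_k(H=0, a).
Standard errors propagate the full parameter covariance through this
functional by the delta method (the posterior responsibilities are
re-evaluated at perturbed parameters); Wald CIs and 2-tailed Wald tests at
the nominal level follow.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import FitResult, ModelParameters, e_step

__all__ = [
    "EffectEstimate", "predict_potential_outcome", "estimate_ate",
    "estimate_subgroup_ate", "wald_interval", "standard_subgroups",
]

SUBGROUP_FLOOR = 30


@dataclass
class EffectEstimate:
    """A risk difference with its Wald uncertainty.

    ``rd`` is on the probability scale in [-1, 1]; the reporting layer is
    the only place it is converted to percentage points.
    """
    outcome: str
    window: int
    population: str
    rd: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    estimator: str = "latent"
    level: float = 0.95
    flags: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"population": self.population, "outcome": self.outcome,
                "window": self.window, "estimator": self.estimator,
                "rd": self.rd, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p_value, "n": self.n,
                "flags": ";".join(sorted(self.flags)) or ""}


def wald_interval(estimate: float, se: float, level: float = 0.95):
    """(low, high, p): estimate +- z*se and the 2-tailed Wald p-value."""
    if not se > 0:
        raise ValueError("se must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    p = 2.0 * norm.sf(abs(estimate) / se)
    return estimate - z * se, estimate + z * se, float(p)


def predict_potential_outcome(params: ModelParameters, gamma, a: int,
                              outcome: str) -> np.ndarray:
    """Posterior-integrated outcome probability under forced decision ``a``.

    gamma is the final E-step responsibility; the latent state is averaged
    over it while every other variable keeps its observed value.
    """
    o = params.outcomes[outcome]
    g = np.asarray(gamma, dtype=float)
    return g * o.prob(1, a) + (1.0 - g) * o.prob(0, a)


def _per_visit_diff(params: ModelParameters, frame: pd.DataFrame,
                    outcome: str) -> np.ndarray:
    gamma = e_step(params, frame)
    return (predict_potential_outcome(params, gamma, 1, outcome)
            - predict_potential_outcome(params, gamma, 0, outcome))


def _rd_functional(params: ModelParameters, frame: pd.DataFrame,
                   outcome: str, mask: np.ndarray | None = None) -> float:
    diff = _per_visit_diff(params, frame, outcome)
    if mask is not None:
        diff = diff[mask]
    return float(np.mean(diff))


def _diff_jacobian(fit: FitResult, frame: pd.DataFrame, outcome: str,
                   step_scale: float = 1e-5) -> np.ndarray:
    """(n x p) central-difference Jacobian of the per-visit counterfactual
    contrast; the posterior gamma is re-evaluated at perturbed parameters,
    so parameter uncertainty flows through the E-step as well.  Cached on
    the fit object keyed by outcome."""
    cache = getattr(fit, "_diff_jac_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(fit, "_diff_jac_cache", cache)
    key = (outcome, len(frame))
    if key in cache:
        return cache[key]
    theta = fit.params.to_vector()
    J = np.empty((len(frame), theta.size))
    for j in range(theta.size):
        h = step_scale * (1.0 + abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (_per_visit_diff(fit.params.from_vector(up), frame, outcome)
                   - _per_visit_diff(fit.params.from_vector(dn), frame,
                                     outcome)) / (2.0 * h)
    cache[key] = J
    return J


def _delta_method_se(fit: FitResult, frame: pd.DataFrame, outcome: str,
                     mask: np.ndarray | None = None) -> float:
    if fit.covariance is None:
        return np.nan
    J = _diff_jacobian(fit, frame, outcome)
    grad = (J.mean(axis=0) if mask is None else J[mask].mean(axis=0))
    var = float(grad @ fit.covariance @ grad)
    return np.sqrt(var) if var > 0 else np.nan


def estimate_ate(fit: FitResult, frame: pd.DataFrame, outcome: str,
                 level: float = 0.95, population: str = "overall",
                 mask: np.ndarray | None = None) -> EffectEstimate:
    """Average treatment effect of admission on ``outcome`` as a risk
    difference, with delta-method Wald interval."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty subgroup '{population}'")
    else:
        n = len(frame)
    rd = _rd_functional(fit.params, frame, outcome, mask)
    se = _delta_method_se(fit, frame, outcome, mask)
    flags = {}
    if mask is not None and n < SUBGROUP_FLOOR:
        flags["below_subgroup_floor"] = True
    if not np.isfinite(se) or se <= 0:
        flags["nonfinite_se"] = True
        lo = hi = np.nan
        p = np.nan
    else:
        lo, hi, p = wald_interval(rd, se, level)
    fam, w = outcome.rsplit("_", 1)
    return EffectEstimate(outcome=fam, window=int(w.rstrip("d")),
                          population=population, rd=rd, se=se, ci_low=lo,
                          ci_high=hi, p_value=p, n=n, estimator="latent",
                          level=level, flags=flags)


def estimate_subgroup_ate(fit: FitResult, frame: pd.DataFrame, outcome: str,
                          predicate, name: str,
                          level: float = 0.95) -> EffectEstimate:
    """ATE restricted to the visits selected by ``predicate``.

    ``predicate`` is either a boolean mask aligned with the frame or a
    callable mapping the frame to one.
    """
    mask = predicate(frame) if callable(predicate) else predicate
    mask = np.asarray(mask, dtype=bool)
    return estimate_ate(fit, frame, outcome, level=level,
                        population=name, mask=mask)


def standard_subgroups(table: pd.DataFrame) -> dict:
    """The report's subgroup axes, on the *unstandardised* cohort table:
    age and HCC split at the sample mean, sex, Medicare vs other insurance,
    and each comorbidity indicator."""
    age_mean = float(table["age"].mean())
    hcc_mean = float(table["hcc"].mean())
    out = {
        f"age<= {age_mean:.1f}": (table["age"] <= age_mean).to_numpy(),
        f"age> {age_mean:.1f}": (table["age"] > age_mean).to_numpy(),
        "male": (table["female"] == 0).to_numpy(),
        "female": (table["female"] == 1).to_numpy(),
        "medicare": (table["insurance"] == "medicare").to_numpy(),
        "insurance_other": (table["insurance"] != "medicare").to_numpy(),
        "no_diabetes": (table["diabetes"] == 0).to_numpy(),
        "diabetes": (table["diabetes"] == 1).to_numpy(),
        "no_chf": (table["chf"] == 0).to_numpy(),
        "chf": (table["chf"] == 1).to_numpy(),
        "no_hypertension": (table["hypertension"] == 0).to_numpy(),
        "hypertension": (table["hypertension"] == 1).to_numpy(),
        f"hcc<= {hcc_mean:.2f}": (table["hcc"] <= hcc_mean).to_numpy(),
        f"hcc> {hcc_mean:.2f}": (table["hcc"] > hcc_mean).to_numpy(),
    }
    return out
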