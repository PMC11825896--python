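"""Non-latent estimators of the same risk differences.

Three reference analyses accompany the latent-variable estimate:

* unadjusted    — the observed admitted-minus-discharged risk difference
                  with the two-proportion Wald standard error;
* IPW           — Hajek (normalized) inverse-probability weighting by a
                  logistic propensity model on the measured variables;
* g-computation — parametric g-formula: a logistic outcome model on
                  (admission, measured variables), standardized over the
                  empirical covariate distribution.

These adjust only for *measured* variables, so under latent-driven
confounding by indication they remain biased — the methodological contrast
the latent model exists to resolve.  IPW and g-computation standard errors
come from a seeded nonparametric bootstrap of the full procedure,
including the model refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BASELINE_COLUMNS, PROXY_COLUMNS
from .effects import EffectEstimate, wald_interval

__all__ = [
    "PropensityFit", "unadjusted_rd", "fit_propensity", "ipw_rd",
    "g_computation_rd", "DEFAULT_ADJUSTMENT_COLUMNS",
]

DEFAULT_ADJUSTMENT_COLUMNS = BASELINE_COLUMNS + PROXY_COLUMNS
_SCORE_EPS = 1e-6
_N_BOOT = 500


@dataclass
class PropensityFit:
    coefficients: np.ndarray
    columns: list
    scores: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _family(outcome: str):
    fam, w = outcome.rsplit("_", 1)
    return fam, int(w.rstrip("d"))


def _estimate(outcome, population, rd, se, n, estimator, level, flags=None):
    flags = flags or {}
    if np.isfinite(se) and se > 0:
        lo, hi, p = wald_interval(rd, se, level)
    else:
        lo = hi = p = np.nan
        flags["nonfinite_se"] = True
    fam, w = _family(outcome)
    return EffectEstimate(outcome=fam, window=w, population=population,
                          rd=rd, se=se, ci_low=lo, ci_high=hi, p_value=p,
                          n=n, estimator=estimator, level=level, flags=flags)


def unadjusted_rd(frame: pd.DataFrame, outcome: str, level: float = 0.95,
                  population: str = "overall") -> EffectEstimate:
    """Observed risk difference with the two-proportion Wald SE."""
    y = frame[outcome].to_numpy(dtype=float)
    a = frame["admitted"].to_numpy(dtype=float)
    n1, n0 = int(np.sum(a == 1)), int(np.sum(a == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both arms must be nonempty")
    p1, p0 = float(np.mean(y[a == 1])), float(np.mean(y[a == 0]))
    rd = p1 - p0
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    return _estimate(outcome, population, rd, se, n1 + n0, "unadjusted",
                     level)


def _logistic_mle(y, design, flags, tag):
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()
                         ).fit(maxiter=100)
            beta = np.asarray(res.params, dtype=float)
        except Exception:
            flags[f"{tag}_failed"] = True
            return None
    lin = design @ beta
    m = float(np.max(np.abs(lin)))
    if not np.all(np.isfinite(beta)) or m > 30.0:
        flags[f"{tag}_separation"] = True
        if np.all(np.isfinite(beta)) and m > 0:
            beta = beta * (30.0 / m)
        else:
            return None
    return beta


def fit_propensity(frame: pd.DataFrame,
                   columns: list | None = None) -> PropensityFit:
    """Logistic model of admission on the measured variables.

    Scores are trimmed into [1e-6, 1 - 1e-6]; diagnostics report the raw
    score range and the Kish effective sample size of each arm's weights.
    """
    cols = (list(columns) if columns is not None
            else list(DEFAULT_ADJUSTMENT_COLUMNS))
    X = np.column_stack([np.ones(len(frame)),
                         frame[cols].to_numpy(dtype=float)])
    a = frame["admitted"].to_numpy(dtype=float)
    flags: dict = {}
    beta = _logistic_mle(a, X, flags, "propensity")
    if beta is None:
        raise RuntimeError("propensity model could not be fitted")
    score = 1.0 / (1.0 + np.exp(-(X @ beta)))
    score = np.clip(score, _SCORE_EPS, 1.0 - _SCORE_EPS)
    w1 = a / score
    w0 = (1.0 - a) / (1.0 - score)
    diag = {
        "score_min": float(score.min()), "score_max": float(score.max()),
        "ess_admitted": float(np.sum(w1) ** 2 / np.sum(w1 ** 2)),
        "ess_discharged": float(np.sum(w0) ** 2 / np.sum(w0 ** 2)),
        **flags,
    }
    return PropensityFit(coefficients=beta, columns=["const"] + cols,
                         scores=score, diagnostics=diag)


def _hajek(y, a, score):
    w1 = a / score
    w0 = (1.0 - a) / (1.0 - score)
    return float(np.sum(w1 * y) / np.sum(w1) - np.sum(w0 * y) / np.sum(w0))


def ipw_rd(frame: pd.DataFrame, outcome: str,
           propensity: PropensityFit | None = None,
           columns: list | None = None, n_boot: int = _N_BOOT,
           seed: int = 0, level: float = 0.95,
           population: str = "overall") -> EffectEstimate:
    """Hajek-weighted risk difference; bootstrap SE over the whole
    procedure including the propensity refit."""
    cols = (list(columns) if columns is not None
            else list(DEFAULT_ADJUSTMENT_COLUMNS))
    if propensity is None:
        propensity = fit_propensity(frame, cols)
    y = frame[outcome].to_numpy(dtype=float)
    a = frame["admitted"].to_numpy(dtype=float)
    rd = _hajek(y, a, propensity.scores)
    flags = {}
    if (propensity.diagnostics.get("ess_admitted", np.inf) < 30
            or propensity.diagnostics.get("ess_discharged", np.inf) < 30):
        flags["low_effective_sample_size"] = True
    se = _bootstrap_se(
        frame, seed, n_boot,
        lambda f: _hajek(f[outcome].to_numpy(dtype=float),
                         f["admitted"].to_numpy(dtype=float),
                         fit_propensity(f, cols).scores))
    return _estimate(outcome, population, rd, se, len(frame), "ipw",
                     level, flags)


def g_computation_rd(frame: pd.DataFrame, outcome: str,
                     columns: list | None = None, n_boot: int = _N_BOOT,
                     seed: int = 0, level: float = 0.95,
                     population: str = "overall") -> EffectEstimate:
    """Parametric g-formula: logistic outcome model on (A, measured
    variables), standardized over the empirical covariate distribution."""
    cols = (list(columns) if columns is not None
            else list(DEFAULT_ADJUSTMENT_COLUMNS))

    def point(f: pd.DataFrame) -> float:
        X = f[cols].to_numpy(dtype=float)
        a = f["admitted"].to_numpy(dtype=float)
        y = f[outcome].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(f)), a, X])
        flags: dict = {}
        beta = _logistic_mle(y, design, flags, "gcomp")
        if beta is None:
            raise RuntimeError("g-computation outcome model failed")
        d1 = np.column_stack([np.ones(len(f)), np.ones(len(f)), X])
        d0 = np.column_stack([np.ones(len(f)), np.zeros(len(f)), X])
        p1 = 1.0 / (1.0 + np.exp(-(d1 @ beta)))
        p0 = 1.0 / (1.0 + np.exp(-(d0 @ beta)))
        return float(np.mean(p1 - p0))

    rd = point(frame)
    se = _bootstrap_se(frame, seed, n_boot, point)
    return _estimate(outcome, population, rd, se, len(frame), "gcomp", level)


def _bootstrap_se(frame: pd.DataFrame, seed: int, n_boot: int, stat) -> float:
    if n_boot <= 0:
        return np.nan
    rng = np.random.default_rng(seed)
    n = len(frame)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        f = frame.iloc[idx]
        try:
            vals.append(stat(f))
        except Exception:
            continue
    if len(vals) < max(10, n_boot // 2):
        return np.nan
    return float(np.std(np.asarray(vals), ddof=1))
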