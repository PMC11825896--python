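"""Joint latent-variable model and its expectation-maximization fit.

The model introduces a binary latent health state H (adverse vs benign) to
absorb confounding by indication in the admission decision:

* latent prior      — logistic regression of H on baseline characteristics;
* proxy models      — linear regression of each continuous vital on
                      (H, baseline) with Gaussian residuals, and logistic
                      regression of the high-acuity (ESI=2) indicator;
* admission process — two-boundary Wiener first-passage likelihood for the
                      (decision, treatment time) pair, drift linear in
                      (H, baseline, proxies);
* outcome models    — identity-link Bernoulli per windowed outcome with
                      admission main effect and latent-by-admission
                      interaction, probabilities clamped to [eps, 1-eps].

Fitting alternates an exact E-step (posterior responsibility of H = 1, in
the log domain) with conditional M-steps: weighted logistic/least-squares
updates in closed form or by IRLS, and a warm-started quasi-Newton update
of the threshold parameters.  Mixture-label ambiguity is resolved by
requiring a nonnegative latent effect on the first continuous proxy
(temperature).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .cohort import BASELINE_COLUMNS, PROXY_COLUMNS, CONTINUOUS_PROXIES
from .preprocessing import OUTCOME_COLUMNS, encode_design
from .wiener import ThresholdParameters, admission_loglik

__all__ = [
    "ProxyParameters", "OutcomeParameters", "ModelParameters", "FitResult",
    "LatentHealthModel", "make_model_frame", "latent_prior",
    "component_loglik", "e_step", "m_step", "fit_em", "observed_loglik",
    "EPS_OUTCOME",
]

EPS_OUTCOME = 1e-6
_LINPRED_CAP = 30.0
_ACUITY_COL = "acuity2"


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class ProxyParameters:
    """x_j = alpha + lam * H + kappa . baseline + N(0, sigma^2)."""
    alpha: float
    lam: float
    kappa: np.ndarray
    sigma: float

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=float)
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class OutcomeParameters:
    """P(Y=1) = clamp(b0 + bh*H + ba*A + bha*H*A, eps, 1-eps)."""
    b0: float
    bh: float
    ba: float
    bha: float = 0.0

    def prob(self, h, a):
        return np.clip(self.b0 + self.bh * h + self.ba * a + self.bha * h * a,
                       EPS_OUTCOME, 1.0 - EPS_OUTCOME)


@dataclass
class ModelParameters:
    eta: np.ndarray                    # latent prior: intercept + baseline
    proxies: dict                      # name -> ProxyParameters
    acuity: np.ndarray                 # logistic: [intercept, lam_h, kappa]
    threshold: ThresholdParameters
    outcomes: dict                     # outcome column -> OutcomeParameters
    flags: dict = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            eta=self.eta.copy(),
            proxies={k: ProxyParameters(v.alpha, v.lam, v.kappa.copy(), v.sigma)
                     for k, v in self.proxies.items()},
            acuity=self.acuity.copy(),
            threshold=ThresholdParameters(
                self.threshold.boundary_a, self.threshold.start_w0,
                self.threshold.delta0, self.threshold.delta_h,
                self.threshold.delta_x.copy(), self.threshold.delta_w.copy()),
            outcomes={k: OutcomeParameters(v.b0, v.bh, v.ba, v.bha)
                      for k, v in self.outcomes.items()},
            flags=dict(self.flags))

    # flat-vector view (used for numerical covariance and delta method)
    def param_names(self) -> list:
        names = [f"eta[{c}]" for c in ["const"] + BASELINE_COLUMNS]
        for p in self.proxies:
            names += [f"{p}.alpha", f"{p}.lam"]
            names += [f"{p}.kappa[{c}]" for c in BASELINE_COLUMNS]
            names += [f"{p}.sigma"]
        names += [f"acuity[{c}]" for c in ["const", "lam_h"] + BASELINE_COLUMNS]
        names += ["threshold.boundary_a", "threshold.start_w0",
                  "threshold.delta0", "threshold.delta_h"]
        names += [f"threshold.delta_x[{c}]" for c in BASELINE_COLUMNS]
        names += [f"threshold.delta_w[{c}]" for c in PROXY_COLUMNS]
        for k in self.outcomes:
            names += [f"{k}.b0", f"{k}.bh", f"{k}.ba", f"{k}.bha"]
        return names

    def to_vector(self) -> np.ndarray:
        parts = [self.eta]
        for p in self.proxies.values():
            parts.append([p.alpha, p.lam])
            parts.append(p.kappa)
            parts.append([p.sigma])
        parts.append(self.acuity)
        parts.append(self.threshold.flat())
        for o in self.outcomes.values():
            parts.append([o.b0, o.bh, o.ba, o.bha])
        return np.concatenate([np.atleast_1d(np.asarray(p, float))
                               for p in parts])

    def from_vector(self, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        out = self.copy()
        i = 0
        nB = len(BASELINE_COLUMNS)
        out.eta = vec[i:i + nB + 1].copy(); i += nB + 1
        for name in out.proxies:
            p = out.proxies[name]
            p.alpha, p.lam = vec[i], vec[i + 1]; i += 2
            p.kappa = vec[i:i + nB].copy(); i += nB
            p.sigma = max(vec[i], 1e-8); i += 1
        out.acuity = vec[i:i + nB + 2].copy(); i += nB + 2
        nW = len(PROXY_COLUMNS)
        out.threshold = ThresholdParameters.from_flat(
            vec[i:i + 4 + nB + nW], nB, nW); i += 4 + nB + nW
        for k in out.outcomes:
            o = out.outcomes[k]
            o.b0, o.bh, o.ba, o.bha = vec[i:i + 4]; i += 4
        assert i == vec.size
        return out

    def to_json(self, path=None):
        d = {
            "eta": self.eta.tolist(),
            "proxies": {k: {"alpha": v.alpha, "lam": v.lam,
                            "kappa": v.kappa.tolist(), "sigma": v.sigma}
                        for k, v in self.proxies.items()},
            "acuity": self.acuity.tolist(),
            "threshold": {
                "boundary_a": self.threshold.boundary_a,
                "start_w0": self.threshold.start_w0,
                "delta0": self.threshold.delta0,
                "delta_h": self.threshold.delta_h,
                "delta_x": self.threshold.delta_x.tolist(),
                "delta_w": self.threshold.delta_w.tolist()},
            "outcomes": {k: {"b0": v.b0, "bh": v.bh, "ba": v.ba, "bha": v.bha}
                         for k, v in self.outcomes.items()},
            "flags": self.flags,
        }
        if path is None:
            return d
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class FitResult:
    params: ModelParameters
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int
    covariance: np.ndarray | None
    param_names: list
    best_of_restarts: int
    posterior: np.ndarray
    n_obs: int
    flags: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "params": self.params.to_json(),
                "loglik_trace": np.asarray(self.loglik_trace).tolist(),
                "converged": bool(self.converged),
                "n_iterations": int(self.n_iterations),
                "best_of_restarts": int(self.best_of_restarts),
                "n_obs": int(self.n_obs),
                "flags": self.flags,
            }, fh, indent=1)


# --------------------------------------------------------------------------
# model frame


def make_model_frame(table: pd.DataFrame,
                     outcome_matrix: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Assemble the numeric frame the model consumes.

    ``table`` must already be filtered, imputed and standardised; the frame
    holds the encoded baseline design, encoded proxies, the admission
    indicator, the treatment time, and any outcome indicator columns.
    """
    frame = encode_design(table)
    frame["admitted"] = (table["decision"] == "admit").astype(float)
    frame["treatment_time"] = table["treatment_time"].astype(float)
    if outcome_matrix is not None:
        for col in outcome_matrix.columns:
            frame[col] = outcome_matrix[col].astype(float).to_numpy()
    return frame


def frame_from_generated(table: pd.DataFrame, config) -> pd.DataFrame:
    """Model frame for a synthetic cohort using the generator's own
    standardisation constants (population scale rather than sample scale).

    Rows with a non-admit/discharge disposition are dropped; SNF/IRF count
    as discharges.  Used for simulation studies where the design should be
    exactly the generating one.
    """
    from .preprocessing import derive_outcome_matrix
    t = table.loc[table["decision"].isin(["admit", "discharge"])
                  & table["acuity"].isin([2, 3])].copy()
    bs = config.baseline_spec
    t["age"] = (t["age"] - bs.age_mean) / bs.age_sd
    t["hcc"] = (t["hcc"] - bs.hcc_mean) / bs.hcc_sd
    for nm, (m, s) in config.proxy_standardization.items():
        t[nm] = (t[nm] - m) / s
    return make_model_frame(t, derive_outcome_matrix(t))


def parameters_from_generator(config, outcome_cols: list) -> ModelParameters:
    """The generating parameters expressed on the model-frame scale.

    Continuous proxies are standardised in the frame, so proxy intercepts,
    latent effects, baseline effects and residual SDs are divided by the
    population SD (intercepts also shifted); window-w outcome coefficients
    are the 30-day ones scaled by w/30 (uniform day-of-event).  Used as the
    reference point in simulation recovery studies.
    """
    from .cohort import CONTINUOUS_PROXIES as _CP
    prox = {}
    for nm in _CP:
        sp = config.proxy_spec[nm]
        m, s = config.proxy_standardization[nm]
        prox[nm] = ProxyParameters(alpha=(sp.alpha - m) / s, lam=sp.lam / s,
                                   kappa=sp.kappa / s, sigma=sp.sigma / s)
    outs = {}
    for col in outcome_cols:
        fam, w = col.rsplit("_", 1)
        f = int(w.rstrip("d")) / 30.0
        sp = config.outcome_spec[fam]
        outs[col] = OutcomeParameters(b0=sp.b0 * f, bh=sp.bh * f,
                                      ba=sp.ba * f, bha=sp.bha * f)
    th = config.threshold_spec
    return ModelParameters(
        eta=config.eta.copy(), proxies=prox, acuity=config.acuity_coef.copy(),
        threshold=ThresholdParameters(th.boundary_a, th.start_w0, th.delta0,
                                      th.delta_h, th.delta_x.copy(),
                                      th.delta_w.copy()),
        outcomes=outs)


def _split(frame: pd.DataFrame):
    X = frame[BASELINE_COLUMNS].to_numpy(dtype=float)
    W = frame[PROXY_COLUMNS].to_numpy(dtype=float)
    A = frame["admitted"].to_numpy(dtype=float)
    T = frame["treatment_time"].to_numpy(dtype=float)
    return X, W, A, T


# --------------------------------------------------------------------------
# likelihood pieces


def latent_prior(eta, baseline) -> np.ndarray:
    """P(H=1 | baseline) = expit(eta . [1, baseline])."""
    eta = np.asarray(eta, dtype=float)
    X = np.atleast_2d(np.asarray(baseline, dtype=float))
    p = expit(eta[0] + X @ eta[1:])
    return p if p.size > 1 else float(p[0])


def component_loglik(params: ModelParameters, frame: pd.DataFrame, h: int,
                     outcomes: list | None = None) -> np.ndarray:
    """Per-visit complete-data log-likelihood at latent state ``h``.

    Sums the log prior, Gaussian proxy densities, the acuity Bernoulli
    term, the admission first-passage density, and the clamped
    identity-link Bernoulli terms of the included outcomes.
    """
    X, W, A, T = _split(frame)
    n = len(frame)
    hv = float(h)

    lin = params.eta[0] + X @ params.eta[1:]
    ll = log_expit(lin) if h == 1 else log_expit(-lin)

    for j, name in enumerate(CONTINUOUS_PROXIES):
        p = params.proxies[name]
        x = frame[f"{name}_z"].to_numpy(dtype=float)
        mu = p.alpha + p.lam * hv + X @ p.kappa
        ll = ll - 0.5 * np.log(2.0 * np.pi) - np.log(p.sigma) \
            - 0.5 * ((x - mu) / p.sigma) ** 2

    ac = frame[_ACUITY_COL].to_numpy(dtype=float)
    lin_ac = params.acuity[0] + params.acuity[1] * hv + X @ params.acuity[2:]
    ll = ll + ac * log_expit(lin_ac) + (1.0 - ac) * log_expit(-lin_ac)

    ll = ll + admission_loglik(params.threshold, X, W,
                               np.full(n, hv), A.astype(int), T)

    keys = list(outcomes if outcomes is not None else params.outcomes)
    for fam, cols in _group_by_family(keys).items():
        if len(cols) == 1:
            o = params.outcomes[cols[0]]
            y = frame[cols[0]].to_numpy(dtype=float)
            p1 = o.prob(hv, A)
            ll = ll + y * np.log(p1) + (1.0 - y) * np.log1p(-p1)
        else:
            # windows of one family are nested truncations of one event, so
            # their joint law is categorical over the increment pattern
            probs = [params.outcomes[c].prob(hv, A) for c in cols]
            ys = [frame[c].to_numpy(dtype=float) for c in cols]
            cell = np.full(n, np.nan)
            prev_p = np.zeros(n)
            prev_y = np.zeros(n)
            for y, p1 in zip(ys, probs):
                newly = (y == 1) & (prev_y == 0)
                inc = np.maximum(p1 - prev_p, EPS_OUTCOME)
                cell = np.where(newly, inc, cell)
                prev_p, prev_y = p1, np.maximum(prev_y, y)
            none = prev_y == 0
            cell = np.where(none, np.maximum(1.0 - probs[-1], EPS_OUTCOME),
                            cell)
            if np.isnan(cell).any():
                raise ValueError(
                    f"outcome family '{fam}' violates window nesting")
            ll = ll + np.log(cell)
    return ll


def _group_by_family(keys: list) -> dict:
    """Group outcome columns (e.g. revisit_3d/_9d/_30d) by family, windows
    sorted ascending."""
    fams: dict = {}
    for k in keys:
        fam, w = k.rsplit("_", 1)
        fams.setdefault(fam, []).append((int(w.rstrip("d")), k))
    return {fam: [k for _, k in sorted(v)] for fam, v in fams.items()}


def e_step(params: ModelParameters, frame: pd.DataFrame) -> np.ndarray:
    """Posterior responsibility gamma_i = P(H_i=1 | everything observed)."""
    l0 = component_loglik(params, frame, 0)
    l1 = component_loglik(params, frame, 1)
    return expit(l1 - l0)


def observed_loglik(params: ModelParameters, frame: pd.DataFrame) -> float:
    l0 = component_loglik(params, frame, 0)
    l1 = component_loglik(params, frame, 1)
    return float(np.sum(logsumexp(np.stack([l0, l1]), axis=0)))


def per_visit_observed_loglik(params: ModelParameters,
                              frame: pd.DataFrame) -> np.ndarray:
    l0 = component_loglik(params, frame, 0)
    l1 = component_loglik(params, frame, 1)
    return logsumexp(np.stack([l0, l1]), axis=0)


# --------------------------------------------------------------------------
# M-step


def _weighted_logistic(y, design, weights, flags, tag):
    """Weighted logistic MLE with a |linear predictor| <= 30 cap."""
    import statsmodels.api as sm
    keep = weights > 1e-12
    ybar = np.sum(weights[keep] * y[keep]) / np.sum(weights[keep])
    if ybar < 1e-9 or ybar > 1.0 - 1e-9:
        # complete separation: the MLE diverges; cap the intercept
        flags[f"{tag}_separation"] = True
        beta = np.zeros(design.shape[1])
        beta[0] = _LINPRED_CAP if ybar > 0.5 else -_LINPRED_CAP
        return beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y[keep], design[keep],
                         family=sm.families.Binomial(),
                         freq_weights=weights[keep]).fit(maxiter=50)
            beta = np.asarray(res.params, dtype=float)
        except Exception:
            flags[f"{tag}_failed"] = True
            return None
    lin = design @ beta
    m = np.max(np.abs(lin))
    if not np.all(np.isfinite(beta)) or m > _LINPRED_CAP:
        flags[f"{tag}_separation"] = True
        if np.all(np.isfinite(beta)) and m > 0:
            beta = beta * (_LINPRED_CAP / m)
        else:
            return None
    return beta


def _weighted_ls(y, design, weights):
    """Closed-form weighted least squares plus weighted residual SD."""
    sw = np.sqrt(weights)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ beta
    sigma = np.sqrt(np.sum(weights * resid ** 2) / np.sum(weights))
    return beta, max(sigma, 1e-3)


def _threshold_q(theta: ThresholdParameters, Xs, Ws, Hs, As, Ts, wts):
    ll = admission_loglik(theta, Xs, Ws, Hs, As, Ts)
    return float(np.sum(wts * ll))


def _m_step_threshold(prev: ThresholdParameters, Xs, Ws, Hs, As, Ts, wts,
                      maxiter: int, flags: dict) -> ThresholdParameters:
    """Quasi-Newton update of the threshold block, warm-started.

    Parameterised as (log a, logit w0, delta...); the drift-coefficient
    gradient is analytic (the drift enters the density only through the
    exponential prefactor), the two geometry partials are central
    differences.
    """
    nB, nW = prev.delta_x.size, prev.delta_w.size
    Z = np.column_stack([np.ones_like(Ts), Hs, Xs, Ws])  # drift design

    def unpack(u):
        return ThresholdParameters(
            boundary_a=float(np.exp(u[0])),
            start_w0=float(expit(u[1])),
            delta0=float(u[2]), delta_h=float(u[3]),
            delta_x=u[4:4 + nB], delta_w=u[4 + nB:])

    def negq_grad(u):
        th = unpack(u)
        mu = Z @ u[2:]
        a, w0 = th.boundary_a, th.start_w0
        ll = admission_loglik(th, Xs, Ws, Hs, As, Ts)
        q = np.sum(wts * ll)
        # analytic drift gradient: d log f / d mu
        dmu = np.where(As == 1, a * (1.0 - w0) - mu * Ts, -a * w0 - mu * Ts)
        g_delta = Z.T @ (wts * dmu)
        # numeric geometry partials
        g_geom = np.empty(2)
        for i, hstep in ((0, 1e-5), (1, 1e-5)):
            up, dn = u.copy(), u.copy()
            up[i] += hstep
            dn[i] -= hstep
            g_geom[i] = (_threshold_q(unpack(up), Xs, Ws, Hs, As, Ts, wts)
                         - _threshold_q(unpack(dn), Xs, Ws, Hs, As, Ts, wts)
                         ) / (2.0 * hstep)
        return -q, -np.concatenate([g_geom, g_delta])

    u0 = np.concatenate([
        [np.log(prev.boundary_a),
         np.log(prev.start_w0 / (1.0 - prev.start_w0))],
        [prev.delta0, prev.delta_h], prev.delta_x, prev.delta_w])
    q0 = _threshold_q(prev, Xs, Ws, Hs, As, Ts, wts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(negq_grad, u0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxls": 20})
    cand = unpack(res.x)
    if _threshold_q(cand, Xs, Ws, Hs, As, Ts, wts) >= q0:
        return cand
    flags["threshold_no_improvement"] = True
    return prev


def _m_step_outcome(y, A, g1, g0, include_interaction: bool,
                    prev: OutcomeParameters) -> OutcomeParameters:
    """Weighted MLE of the clamped identity-link outcome model.

    With the interaction the model is saturated in the four (H, A) cells, so
    the weighted cell means (clamped) are the constrained MLE.  Without it,
    a small numerical maximization is used.
    """
    cells = {}
    for a in (0, 1):
        sel = A == a
        for h, wt in ((1, g1), (0, g0)):
            wsum = np.sum(wt[sel])
            cells[(h, a)] = (np.sum(wt[sel] * y[sel]) / wsum
                             if wsum > 1e-9 else None)
    lo, hi = EPS_OUTCOME, 1.0 - EPS_OUTCOME

    if include_interaction:
        prev_cells = {(h, a): prev.prob(h, a) for h in (0, 1) for a in (0, 1)}
        p = {k: np.clip(v, lo, hi) if v is not None else prev_cells[k]
             for k, v in cells.items()}
        return OutcomeParameters(
            b0=p[(0, 0)], bh=p[(1, 0)] - p[(0, 0)],
            ba=p[(0, 1)] - p[(0, 0)],
            bha=p[(1, 1)] - p[(1, 0)] - p[(0, 1)] + p[(0, 0)])

    def negll(b):
        b0, bh, ba = b
        ll = 0.0
        for (h, a), _ in cells.items():
            sel = A == a
            wt = (g1 if h else g0)[sel]
            p1 = np.clip(b0 + bh * h + ba * a, lo, hi)
            ll += np.sum(wt * (y[sel] * np.log(p1)
                               + (1 - y[sel]) * np.log1p(-p1)))
        return -ll

    start = np.array([prev.b0, prev.bh, prev.ba])
    res = minimize(negll, start, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000})
    if negll(res.x) > negll(start):   # never move downhill
        return OutcomeParameters(b0=start[0], bh=start[1], ba=start[2],
                                 bha=0.0)
    b0, bh, ba = res.x
    return OutcomeParameters(b0=b0, bh=bh, ba=ba, bha=0.0)


def m_step(frame: pd.DataFrame, gamma: np.ndarray,
           previous: ModelParameters, include_interaction: bool = True,
           threshold_maxiter: int = 12) -> ModelParameters:
    """Conditional maximization of every component against fractional weights.

    Each visit contributes with weight gamma_i as H=1 and 1-gamma_i as H=0.
    """
    X, W, A, T = _split(frame)
    n = len(frame)
    g1 = np.clip(np.asarray(gamma, dtype=float), 0.0, 1.0)
    g0 = 1.0 - g1
    out = previous.copy()
    out.flags = {}

    ones = np.ones(n)
    Xc = np.column_stack([ones, X])

    # latent prior: stacked fractional logistic regression
    y_st = np.concatenate([ones, np.zeros(n)])
    d_st = np.vstack([Xc, Xc])
    w_st = np.concatenate([g1, g0])
    beta = _weighted_logistic(y_st, d_st, w_st, out.flags, "eta")
    if beta is not None:
        out.eta = beta

    # continuous proxies: closed-form WLS on the stacked frame
    h_st = np.concatenate([ones, np.zeros(n)])
    d_prox = np.column_stack([np.ones(2 * n), h_st, np.vstack([X, X])])
    for name in CONTINUOUS_PROXIES:
        xval = frame[f"{name}_z"].to_numpy(dtype=float)
        b, sigma = _weighted_ls(np.concatenate([xval, xval]), d_prox, w_st)
        out.proxies[name] = ProxyParameters(
            alpha=float(b[0]), lam=float(b[1]), kappa=b[2:].copy(),
            sigma=float(sigma))

    # acuity indicator: stacked fractional logistic with latent effect
    ac = frame[_ACUITY_COL].to_numpy(dtype=float)
    d_ac = np.column_stack([np.ones(2 * n), h_st, np.vstack([X, X])])
    beta = _weighted_logistic(np.concatenate([ac, ac]), d_ac, w_st,
                              out.flags, "acuity")
    if beta is not None:
        out.acuity = beta

    # threshold block
    Xs, Ws = np.vstack([X, X]), np.vstack([W, W])
    As = np.concatenate([A, A]).astype(int)
    Ts = np.concatenate([T, T])
    out.threshold = _m_step_threshold(
        previous.threshold, Xs, Ws, h_st, As, Ts, w_st,
        maxiter=threshold_maxiter, flags=out.flags)

    # outcomes
    for k in previous.outcomes:
        y = frame[k].to_numpy(dtype=float)
        out.outcomes[k] = _m_step_outcome(
            y, A, g1, g0, include_interaction, previous.outcomes[k])
    return out


# --------------------------------------------------------------------------
# label canonicalization


def canonicalize(params: ModelParameters, gamma: np.ndarray | None = None):
    """Fix the mixture orientation: latent effect on temperature >= 0.

    Swapping H <-> 1-H with the matching parameter transformation leaves
    the observed likelihood unchanged; this picks one orientation.
    """
    first = CONTINUOUS_PROXIES[0]
    if params.proxies[first].lam >= 0:
        return params, gamma
    p = params.copy()
    p.eta = -p.eta
    for prox in p.proxies.values():
        prox.alpha += prox.lam
        prox.lam = -prox.lam
    p.acuity = p.acuity.copy()
    p.acuity[0] += p.acuity[1]
    p.acuity[1] = -p.acuity[1]
    th = p.threshold
    p.threshold = ThresholdParameters(
        th.boundary_a, th.start_w0, th.delta0 + th.delta_h, -th.delta_h,
        th.delta_x, th.delta_w)
    for o in p.outcomes.values():
        o.b0 += o.bh
        o.bh = -o.bh
        o.ba += o.bha
        o.bha = -o.bha
    p.flags["label_flipped"] = True
    return p, (None if gamma is None else 1.0 - gamma)


# --------------------------------------------------------------------------
# initialization


def _initial_params(frame: pd.DataFrame, outcomes: list,
                    gamma0: np.ndarray) -> ModelParameters:
    X, W, A, T = _split(frame)
    n = len(frame)
    nB = len(BASELINE_COLUMNS)
    pbar = float(np.clip(np.mean(gamma0), 0.05, 0.95))
    eta = np.zeros(nB + 1)
    eta[0] = np.log(pbar / (1.0 - pbar))
    proxies = {nm: ProxyParameters(
        alpha=float(np.mean(frame[f"{nm}_z"])), lam=0.1,
        kappa=np.zeros(nB),
        sigma=float(max(np.std(frame[f"{nm}_z"].to_numpy()), 1e-2)))
        for nm in CONTINUOUS_PROXIES}
    acuity = np.zeros(nB + 2)
    p_ac = float(np.clip(np.mean(frame[_ACUITY_COL]), 0.02, 0.98))
    acuity[0] = np.log(p_ac / (1.0 - p_ac))
    acuity[1] = 0.1
    # geometry heuristic: zero-drift mean first-passage time is w0(1-w0)a^2
    w0 = float(np.clip(np.mean(A), 0.05, 0.95))
    a0 = float(np.sqrt(max(np.mean(T), 1e-3) / (w0 * (1.0 - w0))))
    threshold = ThresholdParameters(
        boundary_a=a0, start_w0=w0, delta0=0.0, delta_h=0.1,
        delta_x=np.zeros(nB), delta_w=np.zeros(len(PROXY_COLUMNS)))
    outs = {}
    for k in outcomes:
        y = frame[k].to_numpy(dtype=float)
        p1 = np.clip(np.mean(y[A == 1]) if np.any(A == 1) else np.mean(y),
                     EPS_OUTCOME, 1 - EPS_OUTCOME)
        p0 = np.clip(np.mean(y[A == 0]) if np.any(A == 0) else np.mean(y),
                     EPS_OUTCOME, 1 - EPS_OUTCOME)
        outs[k] = OutcomeParameters(b0=float(p0), bh=0.02,
                                    ba=float(p1 - p0), bha=0.0)
    return ModelParameters(eta=eta, proxies=proxies, acuity=acuity,
                           threshold=threshold, outcomes=outs)


def _initial_gamma(frame: pd.DataFrame, rng: np.random.Generator,
                   perturb: float) -> np.ndarray:
    """Preliminary split of the cohort into tentative latent classes.

    A 2-component Gaussian mixture on the continuous proxy block supplies a
    severity split (oriented so the higher-temperature component is the
    adverse one); blending it with the admission indicator encodes the
    clinical prior that the adverse state is admitted more often, which
    starts EM on the confounding-by-indication side of the likelihood.
    """
    Z = frame[[f"{nm}_z" for nm in CONTINUOUS_PROXIES]].to_numpy(dtype=float)
    gm = GaussianMixture(2, random_state=int(rng.integers(2 ** 31)),
                         n_init=1, max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(Z)
    resp = gm.predict_proba(Z)[:, 1]
    if gm.means_[1][0] < gm.means_[0][0]:
        resp = 1.0 - resp
    gamma0 = np.clip(0.5 * resp + 0.5 * frame["admitted"].to_numpy(),
                     0.02, 0.98)
    if perturb > 0:
        logit = np.log(gamma0 / (1.0 - gamma0))
        logit = logit + perturb * rng.standard_normal(len(gamma0))
        gamma0 = expit(logit)
    return gamma0


# --------------------------------------------------------------------------
# covariance


def score_covariance(params: ModelParameters, frame: pd.DataFrame,
                     step_scale: float = 1e-5):
    """Observed-information estimate from numerically differentiated
    per-visit scores (outer-product-of-gradients form).

    Central differences with step 1e-5 * (1 + |param|).  Returns
    (covariance, positive_definite flag).
    """
    theta = params.to_vector()
    n, p = len(frame), theta.size
    S = np.empty((n, p))
    for j in range(p):
        h = step_scale * (1.0 + abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        lu = per_visit_observed_loglik(params.from_vector(up), frame)
        ld = per_visit_observed_loglik(params.from_vector(dn), frame)
        S[:, j] = (lu - ld) / (2.0 * h)
    info = S.T @ S
    try:
        np.linalg.cholesky(info + 1e-12 * np.eye(p))
        pd_flag = True
    except np.linalg.LinAlgError:
        pd_flag = False
    cov = np.linalg.pinv(info, hermitian=True)
    cov = 0.5 * (cov + cov.T)
    return cov, pd_flag


# --------------------------------------------------------------------------
# the estimator


class LatentHealthModel(BaseEstimator):
    """EM-fitted latent-health mixture for ED disposition analysis.

    Parameters
    ----------
    outcomes : list of outcome indicator columns to model (default: all
        nine present in the frame).
    n_restarts, max_iter, rel_tol : EM schedule; restarts perturb the
        initial responsibilities.
    include_interaction : include the latent-by-admission interaction in
        the outcome models.
    compute_covariance : estimate the parameter covariance after fitting.
    seed : seeds the restart perturbations and any tie-breaking.

    Fitted attributes: ``params_``, ``posterior_``, ``loglik_trace_``,
    ``converged_``, ``n_iterations_``, ``covariance_``, ``param_names_``,
    ``best_of_restarts_``, ``result_``.
    """

    def __init__(self, outcomes=None, n_restarts=10, max_iter=500,
                 rel_tol=1e-8, include_interaction=True,
                 compute_covariance=True, threshold_maxiter=12, seed=0):
        self.outcomes = outcomes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.include_interaction = include_interaction
        self.compute_covariance = compute_covariance
        self.threshold_maxiter = threshold_maxiter
        self.seed = seed

    # sklearn-style: frame is the X; there is no separate y
    def fit(self, frame: pd.DataFrame, y=None) -> "LatentHealthModel":
        outcomes = self.outcomes
        if outcomes is None:
            outcomes = [c for c in OUTCOME_COLUMNS if c in frame.columns]
        if not outcomes:
            raise ValueError("no outcome columns found in the frame")
        missing = [c for c in BASELINE_COLUMNS + PROXY_COLUMNS
                   + ["admitted", "treatment_time"] if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks required columns: {missing}")
        if frame[list(frame.columns)].isna().any().any():
            raise ValueError("frame contains missing values; impute first")

        rng = np.random.default_rng(self.seed)
        best = None
        failures = []
        for r in range(max(1, self.n_restarts)):
            try:
                res = self._run_chain(frame, outcomes, rng,
                                      perturb=0.0 if r == 0 else 1.0)
            except Exception as exc:   # keep going across restarts
                failures.append(f"restart {r}: {exc!r}")
                continue
            if best is None or res["loglik"] > best["loglik"]:
                best = res
                best["restart"] = r
        if best is None:
            raise RuntimeError("all EM restarts failed: "
                               + "; ".join(failures))

        params, gamma = canonicalize(best["params"], best["gamma"])
        cov = None
        pd_flag = True
        if self.compute_covariance:
            cov, pd_flag = score_covariance(params, frame)
        flags = dict(params.flags)
        if not pd_flag:
            flags["covariance_not_pd_bootstrap_recommended"] = True
        self.params_ = params
        self.posterior_ = gamma
        self.loglik_trace_ = np.asarray(best["trace"])
        self.converged_ = best["converged"]
        self.n_iterations_ = len(best["trace"])
        self.covariance_ = cov
        self.param_names_ = params.param_names()
        self.best_of_restarts_ = best["restart"]
        self.result_ = FitResult(
            params=params, loglik_trace=self.loglik_trace_,
            converged=self.converged_, n_iterations=self.n_iterations_,
            covariance=cov, param_names=self.param_names_,
            best_of_restarts=self.best_of_restarts_, posterior=gamma,
            n_obs=len(frame), flags=flags)
        return self

    def _run_chain(self, frame, outcomes, rng, perturb):
        gamma = _initial_gamma(frame, rng, perturb)
        params = _initial_params(frame, outcomes, gamma)
        params = m_step(frame, gamma, params, self.include_interaction,
                        threshold_maxiter=max(self.threshold_maxiter, 30))
        trace = []
        prev_ll = -np.inf
        converged = False
        for it in range(self.max_iter):
            gamma = e_step(params, frame)
            params = m_step(frame, gamma, params, self.include_interaction,
                            threshold_maxiter=self.threshold_maxiter)
            ll = observed_loglik(params, frame)
            trace.append(ll)
            if it > 0 and abs(ll - prev_ll) <= self.rel_tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
        gamma = e_step(params, frame)
        return {"params": params, "gamma": gamma, "trace": trace,
                "loglik": trace[-1], "converged": converged}

    def predict_proba_latent(self, frame: pd.DataFrame) -> np.ndarray:
        """Posterior P(H=1 | observed data) under the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        return e_step(self.params_, frame)


def fit_em(frame: pd.DataFrame, outcomes=None, n_restarts=10, max_iter=500,
           rel_tol=1e-8, seed=0, include_interaction=True,
           compute_covariance=True, threshold_maxiter=12) -> FitResult:
    """Functional wrapper around :class:`LatentHealthModel`."""
    est = LatentHealthModel(
        outcomes=outcomes, n_restarts=n_restarts, max_iter=max_iter,
        rel_tol=rel_tol, include_interaction=include_interaction,
        compute_covariance=compute_covariance,
        threshold_maxiter=threshold_maxiter, seed=seed)
    est.fit(frame)
    return est.result_
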