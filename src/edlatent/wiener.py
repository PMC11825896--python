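"""Two-boundary Wiener first-passage ("threshold regression") model.

The admission process is modelled as a latent evidence process: a Wiener
process with unit diffusion starts at ``z = w0 * a`` between a discharge
boundary at 0 and an admit boundary at ``a`` and drifts with rate ``mu``
(linear in latent health, baseline characteristics, and proxy variables).
The boundary hit first is the disposition decision; the hitting time is the
treatment time.  This yields a joint likelihood for the binary decision and
its timing.

Densities use the standard dual infinite-series representation of the
first-passage-time distribution with automatic small-time / large-time
switching; series are truncated when the next term falls below 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdParameters",
    "upper_hit_probability",
    "fpt_density",
    "fpt_log_density",
    "admission_loglik",
    "simulate_first_passage",
]

_TERM_TOL = 1e-9
_MAX_TERMS = 200
# boundary between small-time and large-time series, in units of t / a^2
_TAU_SWITCH = 0.18


@dataclass
class ThresholdParameters:
    """Parameters of the two-boundary Wiener admission model.

    boundary_a : separation between the discharge boundary (0) and the admit
        boundary, in latent-evidence units (diffusion fixed at 1).
    start_w0   : relative start point in (0, 1); absolute start z = w0 * a.
    delta0     : drift intercept.
    delta_h    : drift effect of the adverse latent health state.
    delta_x    : drift effects of the encoded baseline covariates.
    delta_w    : drift effects of the encoded proxy variables.
    """

    boundary_a: float
    start_w0: float
    delta0: float
    delta_h: float
    delta_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta_w: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.delta_x = np.asarray(self.delta_x, dtype=float)
        self.delta_w = np.asarray(self.delta_w, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.boundary_a > 0:
            raise ValueError("boundary_a must be positive")
        if not 0.0 < self.start_w0 < 1.0:
            raise ValueError("start_w0 must lie strictly inside (0, 1)")

    def drift(self, latent_h, baseline, proxies) -> np.ndarray:
        """Linear drift mu = delta0 + delta_h*h + delta_x.x + delta_w.w."""
        mu = self.delta0 + self.delta_h * np.asarray(latent_h, dtype=float)
        if self.delta_x.size:
            mu = mu + np.asarray(baseline, dtype=float) @ self.delta_x
        if self.delta_w.size:
            mu = mu + np.asarray(proxies, dtype=float) @ self.delta_w
        return mu

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [[self.boundary_a, self.start_w0, self.delta0, self.delta_h],
             self.delta_x, self.delta_w]
        )

    @classmethod
    def from_flat(cls, vec: np.ndarray, n_x: int, n_w: int) -> "ThresholdParameters":
        vec = np.asarray(vec, dtype=float)
        return cls(
            boundary_a=float(vec[0]),
            start_w0=float(vec[1]),
            delta0=float(vec[2]),
            delta_h=float(vec[3]),
            delta_x=vec[4:4 + n_x].copy(),
            delta_w=vec[4 + n_x:4 + n_x + n_w].copy(),
        )


def _validate_geometry(boundary_a, start_w0) -> None:
    if np.any(np.asarray(boundary_a) <= 0):
        raise ValueError("boundary_a must be positive")
    w = np.asarray(start_w0)
    if np.any(w <= 0) or np.any(w >= 1):
        raise ValueError("start_w0 must lie strictly inside (0, 1)")


def upper_hit_probability(drift, boundary_a, start_w0):
    """P(admit boundary hit before discharge boundary).

    Closed form (1 - exp(-2 mu w0 a)) / (1 - exp(-2 mu a)); the zero-drift
    limit is w0.  A series expansion is used when |mu * a| < 1e-5 to avoid
    catastrophic cancellation.
    """
    _validate_geometry(boundary_a, start_w0)
    mu = np.asarray(drift, dtype=float)
    a = np.asarray(boundary_a, dtype=float)
    w = np.asarray(start_w0, dtype=float)
    mu, a, w = np.broadcast_arrays(mu, a, w)
    out = np.empty(mu.shape, dtype=float)

    small = np.abs(mu * a) < 1e-5
    if np.any(small):
        # second-order expansion about mu = 0:
        # w * [1 + mu a (1-w) + (mu a)^2 (1-w)(1-2w)/3]
        m, aa, ww = mu[small], a[small], w[small]
        out[small] = ww * (1.0 + m * aa * (1.0 - ww)
                           + (m * aa) ** 2 * (1.0 - ww) * (1.0 - 2.0 * ww) / 3.0)
    big = ~small
    if np.any(big):
        m, aa, ww = mu[big], a[big], w[big]
        # expm1-based form is stable for both drift signs
        out[big] = np.expm1(-2.0 * m * ww * aa) / np.expm1(-2.0 * m * aa)
    return out if out.ndim else float(out)


def _fzero_small(tau: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-drift, unit-boundary lower-bound FPT density, small-time series."""
    total = np.zeros_like(tau)
    prefac = 1.0 / np.sqrt(2.0 * np.pi * tau ** 3)
    active = np.ones(tau.shape, dtype=bool)
    for k in range(_MAX_TERMS):
        if not np.any(active):
            break
        contrib = np.zeros_like(tau)
        for sgn in ((k,) if k == 0 else (k, -k)):
            c = w + 2.0 * sgn
            contrib = contrib + c * np.exp(-c * c / (2.0 * tau))
        total = np.where(active, total + contrib, total)
        # envelope of the next pair of terms
        nxt = w + 2.0 * (k + 1)
        bound = (np.abs(nxt) + np.abs(w - 2.0 * (k + 1))) * np.exp(
            -(2.0 * (k + 1) - 1.0) ** 2 / (2.0 * tau)
        )
        active = active & (prefac * bound >= _TERM_TOL)
    return np.maximum(prefac * total, 0.0)


def _fzero_large(tau: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-drift, unit-boundary lower-bound FPT density, large-time series."""
    total = np.zeros_like(tau)
    active = np.ones(tau.shape, dtype=bool)
    for k in range(1, _MAX_TERMS + 1):
        if not np.any(active):
            break
        term = k * np.exp(-k * k * np.pi ** 2 * tau / 2.0) * np.sin(k * np.pi * w)
        total = np.where(active, total + term, total)
        bound = (k + 1) * np.exp(-(k + 1) ** 2 * np.pi ** 2 * tau / 2.0)
        active = active & (np.pi * bound >= _TERM_TOL)
    return np.maximum(np.pi * total, 0.0)


def _fzero(tau: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.empty_like(tau)
    small = tau < _TAU_SWITCH
    if np.any(small):
        out[small] = _fzero_small(tau[small], w[small])
    if np.any(~small):
        out[~small] = _fzero_large(tau[~small], w[~small])
    return out


def fpt_log_density(t, drift, boundary_a, start_w0, boundary: str):
    """Log of the defective first-passage-time density at the named boundary.

    ``boundary`` is ``"upper"`` (admit) or ``"lower"`` (discharge).  The
    density integrates over t to the probability of exiting through that
    boundary, so the two marginals together integrate to 1.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    _validate_geometry(boundary_a, start_w0)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    mu = np.asarray(drift, dtype=float)
    a = np.asarray(boundary_a, dtype=float)
    w = np.asarray(start_w0, dtype=float)
    t, mu, a, w = np.broadcast_arrays(t, mu, a, w)
    if boundary == "upper":
        # reflection: upper passage of (mu, w) = lower passage of (-mu, 1-w)
        mu, w = -mu, 1.0 - w
    tau = t / a ** 2
    f0 = _fzero(tau, w)
    logf = (-mu * a * w - mu ** 2 * t / 2.0 - 2.0 * np.log(a)
            + np.log(np.maximum(f0, 1e-300)))
    return logf if logf.ndim else float(logf)


def fpt_density(t, drift, boundary_a, start_w0, boundary: str):
    """Defective first-passage-time density (per unit time)."""
    return np.exp(fpt_log_density(t, drift, boundary_a, start_w0, boundary))


def admission_loglik(theta: ThresholdParameters, baseline, proxies, latent_h,
                     decision, treatment_time):
    """Joint log-likelihood of (decision, treatment time) given covariates.

    ``decision`` is 1 for admit (upper boundary) and 0 for discharge (lower
    boundary); drift is linear in (latent_h, baseline, proxies).  Vectorised
    over visits.
    """
    tt = np.asarray(treatment_time, dtype=float)
    if np.any(tt <= 0):
        raise ValueError("treatment_time must be positive")
    mu = theta.drift(latent_h, baseline, proxies)
    dec = np.asarray(decision)
    mu_b, tt_b = np.broadcast_arrays(mu, tt)
    dec_b = np.broadcast_to(dec, mu_b.shape)
    out = np.empty(mu_b.shape, dtype=float)
    up = dec_b == 1
    if np.any(up):
        out[up] = fpt_log_density(tt_b[up], mu_b[up], theta.boundary_a,
                                  theta.start_w0, "upper")
    if np.any(~up):
        out[~up] = fpt_log_density(tt_b[~up], mu_b[~up], theta.boundary_a,
                                   theta.start_w0, "lower")
    # -inf-safe floor for underflowing densities
    out = np.maximum(out, -690.0)
    return out if out.ndim else float(out)


def simulate_first_passage(drift, boundary_a, start_w0, rng, dt=None,
                           max_tau=60.0):
    """Simulate (decision, time) pairs by first-passage of the Wiener process.

    Euler scheme with a Brownian-bridge crossing correction at every step,
    which removes the leading-order discretisation bias in the absorption
    probability.  ``dt`` defaults to 1e-4 * boundary_a**2.

    Returns (decision, time) arrays; decision is 1 for the admit (upper)
    boundary, 0 for discharge (lower).
    """
    _validate_geometry(boundary_a, start_w0)
    mu = np.atleast_1d(np.asarray(drift, dtype=float)).copy()
    a = float(boundary_a)
    if dt is None:
        dt = 1e-4 * a * a
    n = mu.shape[0]
    x = np.full(n, start_w0 * a)
    decision = np.zeros(n, dtype=np.int64)
    time = np.zeros(n, dtype=float)
    alive = np.arange(n)
    t = 0.0
    sq = np.sqrt(dt)
    max_t = max_tau * a * a
    while alive.size:
        t += dt
        xn = x + mu[alive] * dt + sq * rng.standard_normal(alive.size)
        hit_up = xn >= a
        hit_dn = xn <= 0.0
        inside = ~(hit_up | hit_dn)
        if np.any(inside):
            xi, xo = x[inside], xn[inside]
            # Brownian bridge exit probabilities between consecutive points
            p_up = np.exp(-2.0 * (a - xi) * (a - xo) / dt)
            p_dn = np.exp(-2.0 * xi * xo / dt)
            u = rng.random(xi.size)
            b_up = u < p_up
            b_dn = (~b_up) & (u < p_up + p_dn)
            tmp_up = hit_up[inside].copy()
            tmp_up[b_up] = True
            hit_up[inside] = tmp_up
            tmp_dn = hit_dn[inside].copy()
            tmp_dn[b_dn] = True
            hit_dn[inside] = tmp_dn
        absorbed = hit_up | hit_dn
        if t >= max_t:
            # vanishing-probability stragglers: absorb by current position
            forced = ~absorbed
            hit_up[forced] = x[forced] >= a / 2.0
            absorbed[:] = True
        if np.any(absorbed):
            idx = alive[absorbed]
            decision[idx] = hit_up[absorbed].astype(np.int64)
            # crossing happened somewhere inside the step: midpoint rule
            time[idx] = t - 0.5 * dt
            alive = alive[~absorbed]
            x = xn[~absorbed]
        else:
            x = xn
    if np.isscalar(drift) or np.asarray(drift).ndim == 0:
        return int(decision[0]), float(time[0])
    return decision, time
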