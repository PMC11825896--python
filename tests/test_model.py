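"""The latent-health mixture: likelihood components, E-step enumeration
equivalence, M-step closed forms, EM ascent, and label canonicalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from edlatent import cohort as C
from edlatent import model as M


def naive_component_loglik(params, frame, h):
    """Scalar-loop re-implementation used as the enumeration oracle."""
    from scipy.stats import norm
    from edlatent.wiener import fpt_log_density
    out = []
    for _, row in frame.iterrows():
        x = row[C.BASELINE_COLUMNS].to_numpy(dtype=float)
        pH = expit(params.eta[0] + x @ params.eta[1:])
        ll = np.log(pH if h == 1 else 1.0 - pH)
        for nm in C.CONTINUOUS_PROXIES:
            p = params.proxies[nm]
            ll += norm.logpdf(row[f"{nm}_z"],
                              loc=p.alpha + p.lam * h + x @ p.kappa,
                              scale=p.sigma)
        pa = expit(params.acuity[0] + params.acuity[1] * h
                   + x @ params.acuity[2:])
        ll += np.log(pa if row["acuity2"] == 1 else 1.0 - pa)
        th = params.threshold
        mu = (th.delta0 + th.delta_h * h + x @ th.delta_x
              + row[C.PROXY_COLUMNS].to_numpy(dtype=float) @ th.delta_w)
        bd = "upper" if row["admitted"] == 1 else "lower"
        ll += fpt_log_density(row["treatment_time"], mu, th.boundary_a,
                              th.start_w0, bd)
        # single-window outcomes only in the toy frame
        for k, o in params.outcomes.items():
            p1 = float(np.clip(o.b0 + o.bh * h + o.ba * row["admitted"]
                               + o.bha * h * row["admitted"],
                               M.EPS_OUTCOME, 1 - M.EPS_OUTCOME))
            ll += np.log(p1 if row[k] == 1 else 1.0 - p1)
        out.append(ll)
    return np.array(out)


class TestLatentPrior:
    def test_zero_coefficients_give_half(self):
        x = np.array([[0.3, -1.2, 0.0, 1.0, 0.5, 0, 1, 0, 2.0]])
        assert M.latent_prior(np.zeros(10), x) == pytest.approx(0.5)

    def test_intercept_only_matches_logit(self):
        eta = np.zeros(10)
        eta[0] = np.log(0.3 / 0.7)
        x = np.random.default_rng(0).standard_normal((3, 9))
        assert np.allclose(M.latent_prior(eta, x), 0.3)

    def test_monotone_in_positive_coefficient(self):
        eta = np.zeros(10)
        eta[1] = 0.5
        lo = M.latent_prior(eta, np.array([[0.0] * 9]))
        hi = M.latent_prior(eta, np.array([[1.0] + [0.0] * 8]))
        assert hi > lo


class TestComponentLoglik:
    def test_matches_independent_enumeration(self, toy_frame, toy_params):
        for h in (0, 1):
            fast = M.component_loglik(toy_params, toy_frame, h)
            slow = naive_component_loglik(toy_params, toy_frame, h)
            assert np.allclose(fast, slow, atol=1e-10)

    def test_decoupled_latent_leaves_only_prior_difference(self, toy_frame,
                                                           toy_params):
        p = toy_params.copy()
        for prox in p.proxies.values():
            prox.lam = 0.0
        p.acuity[1] = 0.0
        p.threshold.delta_h = 0.0
        for o in p.outcomes.values():
            o.bh = 0.0
            o.bha = 0.0
        diff = (M.component_loglik(p, toy_frame, 1)
                - M.component_loglik(p, toy_frame, 0))
        X = toy_frame[C.BASELINE_COLUMNS].to_numpy(dtype=float)
        lin = p.eta[0] + X @ p.eta[1:]
        # log pH - log (1-pH) = the logit itself
        assert np.allclose(diff, lin, atol=1e-10)

    def test_exp_components_sum_to_observed_likelihood(self, toy_frame,
                                                       toy_params):
        l0 = M.component_loglik(toy_params, toy_frame, 0)
        l1 = M.component_loglik(toy_params, toy_frame, 1)
        per = M.per_visit_observed_loglik(toy_params, toy_frame)
        assert np.allclose(np.exp(l0) + np.exp(l1), np.exp(per), rtol=1e-12)

    def test_nested_window_likelihood_uses_increments(self, toy_params):
        """With all three windows present, the family contribution is the
        categorical probability of the increment pattern."""
        p = toy_params.copy()
        p.outcomes = {
            "revisit_3d": M.OutcomeParameters(0.02, 0.0, 0.0, 0.0),
            "revisit_9d": M.OutcomeParameters(0.06, 0.0, 0.0, 0.0),
            "revisit_30d": M.OutcomeParameters(0.20, 0.0, 0.0, 0.0),
        }
        base = {c: [0.0] for c in C.BASELINE_COLUMNS}
        base.update({c: [0.0] for c in C.PROXY_COLUMNS})
        base.update({"admitted": [0.0], "treatment_time": [1.0]})
        pats = {(0, 0, 0): 0.80, (0, 0, 1): 0.14, (0, 1, 1): 0.04,
                (1, 1, 1): 0.02}
        for pat, prob in pats.items():
            fr = pd.DataFrame({**base, "revisit_3d": [float(pat[0])],
                               "revisit_9d": [float(pat[1])],
                               "revisit_30d": [float(pat[2])]})
            with_out = M.component_loglik(p, fr, 0)
            without = M.component_loglik(p, fr, 0, outcomes=[])
            assert (with_out - without)[0] == pytest.approx(np.log(prob),
                                                            abs=1e-10)


class TestEStep:
    def test_matches_brute_force_enumeration(self, toy_frame, toy_params):
        l0 = naive_component_loglik(toy_params, toy_frame, 0)
        l1 = naive_component_loglik(toy_params, toy_frame, 1)
        brute = np.exp(l1) / (np.exp(l0) + np.exp(l1))
        assert np.allclose(M.e_step(toy_params, toy_frame), brute,
                           atol=1e-12)

    def test_uninformative_model_returns_prior(self, toy_frame, toy_params):
        p = toy_params.copy()
        for prox in p.proxies.values():
            prox.lam = 0.0
        p.acuity[1] = 0.0
        p.threshold.delta_h = 0.0
        for o in p.outcomes.values():
            o.bh = 0.0
            o.bha = 0.0
        X = toy_frame[C.BASELINE_COLUMNS].to_numpy(dtype=float)
        assert np.allclose(M.e_step(p, toy_frame),
                           M.latent_prior(p.eta, X), atol=1e-12)

    def test_invariant_to_common_loglik_shift(self, toy_frame, toy_params):
        l0 = M.component_loglik(toy_params, toy_frame, 0)
        l1 = M.component_loglik(toy_params, toy_frame, 1)
        g = expit(l1 - l0)
        shifted = expit((l1 + 123.4) - (l0 + 123.4))
        assert np.allclose(g, shifted, atol=1e-12)


class TestObservedLoglik:
    def test_matches_enumeration_on_toy(self, toy_frame, toy_params):
        l0 = naive_component_loglik(toy_params, toy_frame, 0)
        l1 = naive_component_loglik(toy_params, toy_frame, 1)
        expected = float(np.sum(np.log(np.exp(l0) + np.exp(l1))))
        assert M.observed_loglik(toy_params, toy_frame) == pytest.approx(
            expected, abs=1e-10)

    def test_duplicated_row_doubles_contribution(self, toy_frame,
                                                 toy_params):
        single = toy_frame.iloc[[0]]
        double = pd.concat([single, single], ignore_index=True)
        assert M.observed_loglik(toy_params, double) == pytest.approx(
            2 * M.observed_loglik(toy_params, single), rel=1e-12)

    def test_invariant_under_row_permutation(self, toy_frame, toy_params):
        perm = toy_frame.iloc[::-1].reset_index(drop=True)
        assert M.observed_loglik(toy_params, perm) == pytest.approx(
            M.observed_loglik(toy_params, toy_frame), rel=1e-12)


class TestMStep:
    def test_proxy_update_equals_normal_equations(self, small_frame):
        rng = np.random.default_rng(0)
        gamma = rng.random(len(small_frame))
        prev = M._initial_params(small_frame, ["revisit_30d"], gamma)
        new = M.m_step(small_frame, gamma, prev, threshold_maxiter=1)
        X = small_frame[C.BASELINE_COLUMNS].to_numpy(dtype=float)
        n = len(small_frame)
        h = np.concatenate([np.ones(n), np.zeros(n)])
        D = np.column_stack([np.ones(2 * n), h, np.vstack([X, X])])
        w = np.concatenate([gamma, 1 - gamma])
        y = np.concatenate([small_frame["temperature_z"]] * 2)
        beta = np.linalg.solve(D.T @ (D * w[:, None]), D.T @ (w * y))
        p = new.proxies["temperature"]
        got = np.concatenate([[p.alpha, p.lam], p.kappa])
        assert np.allclose(got, beta, atol=1e-10)

    def test_degenerate_weights_flag_separation(self, small_frame):
        prev = M._initial_params(small_frame, ["revisit_30d"],
                                 np.full(len(small_frame), 0.5))
        new = M.m_step(small_frame, np.ones(len(small_frame)), prev,
                       threshold_maxiter=1)
        assert new.flags.get("eta_separation", False)
        X = small_frame[C.BASELINE_COLUMNS].to_numpy(dtype=float)
        lin = new.eta[0] + X @ new.eta[1:]
        assert np.max(np.abs(lin)) <= 30.0 + 1e-9

    def test_saturated_outcome_update_is_weighted_cell_means(self,
                                                             small_frame):
        rng = np.random.default_rng(1)
        gamma = rng.random(len(small_frame))
        prev = M._initial_params(small_frame, ["readmission_30d"], gamma)
        new = M.m_step(small_frame, gamma, prev, threshold_maxiter=1)
        y = small_frame["readmission_30d"].to_numpy(dtype=float)
        A = small_frame["admitted"].to_numpy(dtype=float)
        o = new.outcomes["readmission_30d"]
        for h, a in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            w = (gamma if h else 1 - gamma)[A == a]
            expect = np.sum(w * y[A == a]) / np.sum(w)
            assert o.prob(h, a) == pytest.approx(expect, abs=1e-12)


class TestFitEm:
    @pytest.fixture(scope="class")
    def quick_fit(self, small_frame):
        return M.fit_em(small_frame, n_restarts=1, max_iter=25,
                        rel_tol=1e-6, seed=0, compute_covariance=True,
                        threshold_maxiter=8)

    def test_loglik_trace_is_nondecreasing(self, quick_fit):
        tr = np.asarray(quick_fit.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_canonical_orientation(self, quick_fit):
        assert quick_fit.params.proxies["temperature"].lam >= 0

    def test_label_swap_preserves_observed_loglik(self, quick_fit,
                                                  small_frame):
        p = quick_fit.params.copy()
        p.proxies["temperature"].lam *= -1  # force the flip branch
        flipped, _ = M.canonicalize(p)
        ll = M.observed_loglik(p, small_frame)
        # flipping the flipped-back copy twice must preserve the likelihood
        assert M.observed_loglik(flipped, small_frame) == pytest.approx(
            ll, abs=1e-6 * abs(ll))

    def test_covariance_symmetric_psd(self, quick_fit):
        cov = quick_fit.covariance
        assert np.allclose(cov, cov.T, atol=1e-12)
        evals = np.linalg.eigvalsh(cov)
        assert evals.min() > -1e-8 * max(evals.max(), 1.0)

    def test_posterior_tracks_latent_state(self, quick_fit, small_cohort):
        cfg, table, gt = small_cohort
        keep = (table["decision"].isin(["admit", "discharge"])
                & table["acuity"].isin([2, 3])).to_numpy()
        H = gt.latent_states[keep]
        r = np.corrcoef(quick_fit.posterior, H)[0, 1]
        assert r > 0.5

    def test_same_seed_reproduces_fit(self, small_frame):
        f1 = M.fit_em(small_frame, n_restarts=1, max_iter=5, rel_tol=1e-6,
                      seed=11, compute_covariance=False)
        f2 = M.fit_em(small_frame, n_restarts=1, max_iter=5, rel_tol=1e-6,
                      seed=11, compute_covariance=False)
        assert np.array_equal(f1.params.to_vector(), f2.params.to_vector())
        assert np.array_equal(f1.loglik_trace, f2.loglik_trace)

    def test_vector_round_trip(self, quick_fit):
        vec = quick_fit.params.to_vector()
        back = quick_fit.params.from_vector(vec)
        assert np.array_equal(back.to_vector(), vec)
        assert len(quick_fit.param_names) == vec.size

    def test_missing_values_rejected(self, small_frame):
        broken = small_frame.copy()
        broken.loc[0, "temperature_z"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            M.LatentHealthModel(n_restarts=1).fit(broken)

    def test_sklearn_param_interface(self):
        est = M.LatentHealthModel(max_iter=7)
        assert est.get_params()["max_iter"] == 7
        est.set_params(seed=3)
        assert est.seed == 3
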