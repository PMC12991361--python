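"""Priors, sequence likelihood (against an independent oracle), and MAP fitting."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

import gazerl as g
from gazerl.inference import BOUNDS, PRIORS, _SeqData, _batch_objective, log_prior
from gazerl.linking import PARAM_NAMES


MASK8 = g.get_model(8).free_params


class TestLogPrior:
    def test_matches_closed_form_beta_density(self):
        p = g.Params(alpha=0.2, wrel=0.5, beta_q=1.0, beta_gaze=0.5, theta=10.0,
                     A=500.0, b_sep=500.0, t0=150.0)
        got = log_prior(p, ["wrel"])
        # Beta(1.1, 1.1) density at 0.5, written out from the definition
        from math import gamma as G, log

        dens = (0.5 ** 0.1) * (0.5 ** 0.1) * G(2.2) / (G(1.1) * G(1.1))
        assert got == pytest.approx(log(dens), rel=1e-12)

    def test_out_of_support_is_minus_inf(self):
        p = {"alpha": 1.5, "wrel": 0.5}
        assert log_prior(p, ["alpha"]) == -math.inf

    def test_masked_parameter_is_ignored(self):
        a = {"alpha": 0.2, "theta": 5.0}
        b = {"alpha": 0.2, "theta": 99.0}
        mask = ["alpha"]
        assert log_prior(a, mask) == log_prior(b, mask)

    def test_prior_moments_match_specification(self):
        # shape-scale Gammas: mean = k * theta
        assert PRIORS["A"].mean() == pytest.approx(600.0)
        assert PRIORS["t0"].mean() == pytest.approx(180.0)
        assert PRIORS["beta_q"].mean() == pytest.approx(1.0)
        assert PRIORS["alpha"].mean() == pytest.approx(1.3 / 5.0)


def oracle_loglik(params, trials, model_id):
    """Straight-line reference: learning, linking, and LBA written out
    from first principles with no shared code with the package."""
    s = 0.1

    def norm(x, lo, hi):
        return 0.5 if hi - lo <= 0 else (x - lo) / (hi - lo)

    def phi(x):
        return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)

    def fpt_pdf(t, v, A, b):
        if A <= 1e-6:
            return b / (s * t * t) * phi((t * v - b) / (t * s))
        u1, u2 = (b - A - t * v) / (t * s), (b - t * v) / (t * s)
        return max(0.0, (-v * ndtr(u1) + s * phi(u1) + v * ndtr(u2) - s * phi(u2)) / A)

    def fpt_cdf(t, v, A, b):
        if A <= 1e-6:
            return ndtr((t * v - b) / (t * s))
        u1, u2 = (b - A - t * v) / (t * s), (b - t * v) / (t * s)
        c = 1 + (b - A - t * v) / A * ndtr(u1) - (b - t * v) / A * ndtr(u2) \
            + t * s / A * (phi(u1) - phi(u2))
        return min(1.0, max(0.0, c))

    q = {}
    gmin, gmax = math.inf, -math.inf
    total = 0.0
    for tr in trials:
        for o in tr.shown:
            q.setdefault(o, 0.5)
        # likelihood before this trial's update
        if 250.0 <= tr.rt_ms <= 10_000.0:
            qa = [q[o] for o in tr.avail]
            ga = [tr.gaze.get(o, 0.0) for o in tr.avail]
            if model_id == 8:
                e = [math.exp(params.theta * (qa[i] + params.beta_gaze * ga[i])) for i in range(2)]
                v = [params.beta_q * e[i] / sum(e) for i in range(2)]
            elif model_id == 7:
                e = [math.exp(params.theta * qa[i]) for i in range(2)]
                v = [params.beta_q * e[i] / sum(e) + params.beta_gaze * ga[i] for i in range(2)]
            elif model_id == 1:
                v = [params.beta_q * qa[i] for i in range(2)]
            else:
                raise NotImplementedError
            b = params.A + params.b_sep
            t = tr.rt_ms - params.t0
            if t <= 0:
                total += math.log(1e-29)
            else:
                c = tr.avail.index(tr.choice)
                dens = fpt_pdf(t, v[c], params.A, b) * (1 - fpt_cdf(t, v[1 - c], params.A, b))
                total += math.log(max(dens, 1e-29))
        if tr.phase == "learning":
            xs = {o: tr.outcomes[o] for o in tr.shown}
            gmin, gmax = min(gmin, min(xs.values())), max(gmax, max(xs.values()))
            lmin, lmax = min(xs.values()), max(xs.values())
            for o, x in xs.items():
                R = (1 - params.wrel) * norm(x, gmin, gmax) + params.wrel * norm(x, lmin, lmax)
                q[o] = q[o] + params.alpha * (R - q[o])
    return total


class TestSequenceLoglik:
    def test_matches_independent_oracle(self, exp2_agent):
        params, trials = exp2_agent
        sub = trials[:20]
        assert g.sequence_loglik(params, sub, 8) == pytest.approx(
            oracle_loglik(params, sub, 8), abs=1e-8
        )

    @pytest.mark.parametrize("mid", [1, 7, 8])
    def test_batch_engine_matches_scalar_path(self, exp2_agent, mid):
        params, trials = exp2_agent
        model = g.get_model(mid)
        seq = _SeqData(trials)
        free = list(model.free_params)
        fun = _batch_objective(seq, model, free, {})
        theta = np.array([[getattr(params, n) for n in free]])
        neg = float(fun(theta)[0])
        ref = -(g.sequence_loglik(params, trials, mid) + log_prior(params, free))
        assert neg == pytest.approx(ref, rel=1e-10)

    def test_empty_sequence_gives_zero(self, exp2_agent):
        params, _ = exp2_agent
        assert g.sequence_loglik(params, [], 8) == 0.0

    def test_additivity_when_learning_frozen(self, exp2_agent):
        params, trials = exp2_agent
        p0 = g.Params(**{**params.to_dict(), "alpha": 0.0})
        sub = trials[:10]
        one = g.sequence_loglik(p0, sub, 8)
        two = g.sequence_loglik(p0, list(sub) + list(sub), 8)
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_skipped_rts_excluded_but_still_teach(self, exp2_agent):
        from dataclasses import replace

        params, trials = exp2_agent
        sub = list(trials[:10])
        fast = replace(sub[4], rt_ms=100.0)  # below the admissible window
        mod = sub[:4] + [fast] + sub[5:]
        # excluded from the likelihood...
        expected = sum(
            g.trial_logdensity(params, mod, 8, i) for i in range(10) if i != 4
        )
        assert g.sequence_loglik(params, mod, 8) == pytest.approx(expected, rel=1e-9)
        # ...but its outcomes still drive learning
        traj = g.run_learning(mod, params.learn())
        assert traj[5].q != traj[4].q


class TestFitMap:
    def test_refit_same_seed_is_identical(self, exp2_agent):
        params, trials = exp2_agent
        de = g.DESettings(popsize=16, itermax=30, steptol=10)
        a = g.fit_map(trials[:40], 8, de=de, seed=5)
        b = g.fit_map(trials[:40], 8, de=de, seed=5)
        assert a.params == b.params
        assert a.log_posterior == b.log_posterior

    def test_estimates_respect_bounds_and_mask(self, exp2_agent):
        _, trials = exp2_agent
        de = g.DESettings(popsize=16, itermax=30, steptol=10)
        fit = g.fit_map(trials[:40], 4, de=de, seed=5, fixed={"wrel": 0.0})
        p = fit.params
        for n in PARAM_NAMES:
            lo, hi = BOUNDS[n]
            assert lo <= getattr(p, n) <= hi
        assert p.wrel == 0.0
        assert p.beta_gaze == 0.0  # not in model 4's mask

    def test_optimum_at_least_as_good_as_truth(self, exp2_agent):
        params, trials = exp2_agent
        de = g.DESettings(popsize=40, itermax=200, steptol=60)
        fit = g.fit_map(trials, 8, de=de, seed=3)
        truth = g.sequence_loglik(params, trials, 8) + log_prior(params, MASK8)
        assert fit.log_posterior >= truth - 1.0

    def test_alpha_zero_generator_recovered_near_corner(self, exp2_design):
        p = g.Params(alpha=0.0, wrel=0.0, beta_q=0.6, beta_gaze=0.3, theta=12.0,
                     A=400, b_sep=450, t0=150)
        out = g.generate_outcomes(exp2_design, seed=1)
        trials = g.simulate_agent(exp2_design, out, p, 8, seed=2)
        fit = g.fit_map(trials, 8, de=g.DESettings(popsize=40, itermax=200, steptol=60), seed=4)
        assert fit.params.alpha < 0.05

    def test_no_usable_trials_raises(self, exp2_agent):
        from dataclasses import replace

        _, trials = exp2_agent
        fast = [replace(t, rt_ms=50.0) for t in trials[:6]]
        with pytest.raises(ValueError, match="usable"):
            g.fit_map(fast, 8, seed=0)

    def test_fit_counts_skipped_trials(self, exp2_agent):
        from dataclasses import replace

        _, trials = exp2_agent
        mod = [replace(trials[0], rt_ms=20_000.0)] + list(trials[1:30])
        fit = g.fit_map(mod, 1, de=g.DESettings(popsize=12, itermax=15, steptol=8), seed=0)
        assert fit.n_skipped == 1 and fit.n_used == 29


class TestSamplePrior:
    def test_draws_respect_mask_and_bounds(self, rng):
        for _ in range(50):
            p = g.sample_prior(rng, model=4)
            assert p.beta_gaze == 0.0
            for n in g.get_model(4).free_params:
                lo, hi = BOUNDS[n]
                assert lo <= getattr(p, n) <= hi
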