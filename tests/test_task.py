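"""Synthetic task designs, outcome generation, gaze generator, agent simulation."""

import numpy as np
import pytest

import gazerl as g
from gazerl.task import GazeGenConfig, generate_gaze


class TestBuildDesign:
    def test_exp1_structure(self, exp1_design):
        d = exp1_design
        assert len(d.learning_schedule) == 60
        assert len(d.contexts) == 2
        assert all(len(ids) == 4 for ids in d.contexts.values())
        # each of the 12 within-context pairs appears exactly 5 times
        from collections import Counter

        pairs = Counter((ctx, tuple(sorted(p))) for ctx, p in d.learning_schedule)
        assert len(pairs) == 12 and set(pairs.values()) == {5}
        # availability stays within the trial's context
        for ctx, p in d.learning_schedule:
            assert set(p) <= set(d.contexts[ctx])

    def test_exp2_structure(self, exp2_design):
        d = exp2_design
        assert len(d.learning_schedule) == 120
        assert len(d.transfer_schedule) == 112
        assert len({tuple(sorted(p)) for p in d.transfer_schedule}) == 28
        assert len(d.contexts) == 4
        # the printed pair: B (EV 18) better than A locally; C (EV 21) worse than D
        assert d.evs["B"] == 18 and d.evs["C"] == 21
        assert d.ranks["B"] == 1 and d.ranks["C"] == 0

    def test_seed_controls_interleaving(self):
        a = g.build_design("exp2", seed=1)
        b = g.build_design("exp2", seed=1)
        c = g.build_design("exp2", seed=2)
        assert a.learning_schedule == b.learning_schedule
        assert a.learning_schedule != c.learning_schedule

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown experiment"):
            g.build_design("exp3")

    def test_ev_mismatch_raises(self):
        with pytest.raises(ValueError):
            g.build_design("exp1", config={"evs": {"neg": (1, 2, 3, 4)}})


class TestGenerateOutcomes:
    def test_integer_outcomes_for_all_shown(self, exp2_design):
        tab = g.generate_outcomes(exp2_design, seed=0)
        for t, (ctx, _) in enumerate(exp2_design.learning_schedule):
            for oid in exp2_design.shown(ctx):
                assert isinstance(tab.outcomes[(t, oid)], int)

    def test_deterministic_given_seed(self, exp2_design):
        assert g.generate_outcomes(exp2_design, seed=5).outcomes == \
            g.generate_outcomes(exp2_design, seed=5).outcomes

    def test_sd_zero_degenerates_to_ev(self):
        d = g.build_design("exp2", config={"sd": 0.0}, seed=0)
        tab = g.generate_outcomes(d, seed=0)
        evs = d.evs
        assert all(x == round(evs[oid]) for (t, oid), x in tab.outcomes.items())

    def test_mean_outcome_near_ev(self, exp2_design):
        tab = g.generate_outcomes(exp2_design, seed=3)
        xs = [x for (t, oid), x in tab.outcomes.items() if oid == "C"]
        assert len(xs) == 30
        # SD = 2 over 30 draws: sampling error ~ 2/sqrt(30)
        assert abs(np.mean(xs) - 21.0) < 1.5


class TestGenerateGaze:
    def test_symmetric_config_has_half_mean(self, rng):
        cfg = GazeGenConfig(gamma0=0, gamma1=0, gamma2=0, kappa=5, p_zero=0)
        draws = np.array([generate_gaze([0.3, 0.7], 0.5, cfg, rng) for _ in range(4000)])
        assert draws.sum(axis=1) == pytest.approx(1.0)
        assert abs(draws[:, 0].mean() - 0.5) < 0.02

    def test_p_zero_one_always_blank(self, rng):
        cfg = GazeGenConfig(p_zero=1.0)
        for _ in range(20):
            assert generate_gaze([0.2, 0.8], 0.1, cfg, rng).tolist() == [0.0, 0.0]

    def test_higher_q_attracts_gaze(self, rng):
        cfg = GazeGenConfig(gamma0=0, gamma1=2.0, gamma2=0, kappa=5, p_zero=0)
        draws = np.array([generate_gaze([0.2, 0.7], 0.5, cfg, rng) for _ in range(10_000)])
        assert draws[:, 1].mean() > 0.5


class TestSimulateAgent:
    def test_alpha_zero_keeps_values_static(self, exp2_design):
        p = g.Params(alpha=0.0, wrel=0.0, beta_q=1.0, A=300, b_sep=400, t0=150)
        out = g.generate_outcomes(exp2_design, seed=1)
        trials = g.simulate_agent(exp2_design, out, p, 1, seed=2)
        traj = g.run_learning(trials, p.learn())
        assert all(all(v == 0.5 for v in s.q.values()) for s in traj)

    def test_reproducible_given_seed(self, exp2_design):
        p = g.Params(alpha=0.2, wrel=0.5, beta_q=0.4, beta_gaze=0.3, theta=9.0,
                     A=500, b_sep=450, t0=140)
        out = g.generate_outcomes(exp2_design, seed=1)
        a = g.simulate_agent(exp2_design, out, p, 8, seed=9)
        b = g.simulate_agent(exp2_design, out, p, 8, seed=9)
        assert a == b

    def test_trial_counts_and_phases(self, exp2_agent):
        _, trials = exp2_agent
        assert sum(t.phase == "learning" for t in trials) == 120
        assert sum(t.phase == "transfer" for t in trials) == 112
        assert all(not t.outcomes for t in trials if t.phase == "transfer")

    def test_learning_is_choice_independent(self, exp2_design):
        # Full feedback: two runs with different choice RNG streams but the
        # same outcome table must produce the same value trajectory.
        p = g.Params(alpha=0.3, wrel=0.4, beta_q=0.4, beta_gaze=0.3, theta=9.0,
                     A=500, b_sep=450, t0=140)
        out = g.generate_outcomes(exp2_design, seed=1)
        t1 = g.simulate_agent(exp2_design, out, p, 8, seed=101)
        t2 = g.simulate_agent(exp2_design, out, p, 8, seed=202)
        q1 = g.run_learning(t1, p.learn())[-1].q
        q2 = g.run_learning(t2, p.learn())[-1].q
        assert q1 == pytest.approx(q2)

    def test_strong_gaze_shifts_choices(self, exp2_design):
        # Forcing gaze to one option under a large additive gaze weight must
        # raise that option's choice share relative to neutral gaze.
        p = g.Params(alpha=0.0, wrel=0.0, beta_q=0.3, beta_gaze=0.6, theta=0.0,
                     A=300, b_sep=500, t0=150)
        rp = p.race()
        rng = np.random.default_rng(0)
        q = np.array([0.5, 0.5])
        v_fav = g.drift_rates(3, q, np.array([1.0, 0.0]), p).v
        v_neu = g.drift_rates(3, q, np.array([0.5, 0.5]), p).v
        c_fav, _ = g.simulate_trials(v_fav, rp, rng, n=2000)
        c_neu, _ = g.simulate_trials(v_neu, rp, rng, n=2000)
        assert (c_fav == 0).mean() > (c_neu == 0).mean() + 0.1


class TestPopulationGazeProperties:
    def test_correct_option_gaze_advantage_grows(self, exp2_design):
        """Mean gaze-difference for the correct option is positive and rises."""
        p = g.Params(alpha=0.3, wrel=0.0, beta_q=0.4, beta_gaze=0.3, theta=9.0,
                     A=500, b_sep=450, t0=140)
        evs = exp2_design.evs
        early, late = [], []
        for s in range(30):
            out = g.generate_outcomes(exp2_design, seed=1000 + s)
            trials = [t for t in g.simulate_agent(exp2_design, out, p, 8, seed=2000 + s)
                      if t.phase == "learning"]
            for t in trials:
                corr = max(t.avail, key=lambda o: evs[o])
                d = t.gaze[corr] - t.gaze[[o for o in t.avail if o != corr][0]]
                (early if t.trial < 60 else late).append(d)
        assert np.mean(early) > 0
        assert np.mean(late) > np.mean(early)

    def test_learning_curve_rises_above_chance(self, exp1_design):
        """Accuracy under softmax(Q)+gaze with plausible parameters rises
        from near chance toward well above it."""
        p = g.Params(alpha=0.3, wrel=0.0, beta_q=0.28, beta_gaze=0.27, theta=18.35,
                     A=615.96, b_sep=453.53, t0=135.13)
        evs = exp1_design.evs
        accs = np.zeros((25, 60))
        for s in range(25):
            out = g.generate_outcomes(exp1_design, seed=100 + s)
            trials = g.simulate_agent(exp1_design, out, p, 7, seed=200 + s)
            for t in trials:
                ev0, ev1 = evs[t.avail[0]], evs[t.avail[1]]
                if ev0 == ev1:
                    accs[s, t.trial] = np.nan
                    continue
                corr = t.avail[0] if ev0 > ev1 else t.avail[1]
                accs[s, t.trial] = float(t.choice == corr)
        curve = np.nanmean(accs, axis=0)
        # before any feedback only the slight gaze bias separates the options
        assert curve[0] < 0.65
        assert np.nanmean(curve[-15:]) > 0.7
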