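"""Win-stay coding/regression, condition comparisons, learning curves, companions."""

import warnings

import numpy as np
import pandas as pd
import pytest

import revlearn as rl
from helpers import make_session


def _betas_frame(rng, n_subjects, conditions, shift=None, n_blocks=4, sd=1.0):
    """Synthetic per-subject x condition x block coefficient table."""
    rows = []
    for s in range(n_subjects):
        for cond in conditions:
            for b in range(n_blocks):
                mu = (shift or {}).get((cond, b), (shift or {}).get(cond, 0.0))
                rows.append({"subject": f"s{s:02d}", "condition": cond, "block": b,
                             "beta_reward": rng.normal(mu, sd)})
    return pd.DataFrame(rows)


class TestCodeWinstay:
    def test_toy_block_matches_hand_enumeration(self):
        # pairs AB,BC,CA,AB; choices B,B,C,B; rewards 1,0,1,-
        trials = make_session(
            pairs=[(0, 1), (1, 2), (2, 0), (0, 1)],
            choices=[1, 1, 2, 1],
            outcomes=[1, 0, 1, 1],
        )
        coding = rl.code_winstay(trials)
        # t=0 rewarded, B shown at t=1 and chosen again -> +1
        # t=1 unrewarded -> 0; t=2 rewarded, C absent from pair AB at t=3 -> 0
        assert coding["winstay"].tolist() == [1, 0, 0]
        assert coding["valid"].all()

    def test_win_switch_coded_minus_one(self):
        trials = make_session(pairs=[(0, 1), (0, 1)], choices=[0, 1], outcomes=[1, 0])
        assert rl.code_winstay(trials)["winstay"].tolist() == [-1]

    def test_exhaustive_two_trial_truth_table(self):
        # all reward x availability x stay combinations against the coding rule
        for rewarded in (0, 1):
            for available in (False, True):
                for stays in (False, True):
                    first_pair = (0, 1)
                    chosen_first = 0
                    second_pair = (0, 2) if available else (1, 2)
                    if available:
                        chosen_second = 0 if stays else 2
                    else:
                        chosen_second = 1 if stays else 2  # 'stay' meaningless here
                    trials = make_session(
                        pairs=[first_pair, second_pair],
                        choices=[chosen_first, chosen_second],
                        outcomes=[rewarded, 0],
                    )
                    expected = 0
                    if rewarded and available:
                        expected = 1 if stays else -1
                    assert rl.code_winstay(trials)["winstay"].tolist() == [expected], \
                        (rewarded, available, stays)

    def test_lost_trial_invalidates_pair(self):
        trials = make_session(pairs=[(0, 1), (0, 1), (0, 1)],
                              choices=[0, None, 0], outcomes=[1, None, 1],
                              lost=[False, True, False])
        coding = rl.code_winstay(trials)
        assert coding["valid"].tolist() == [False, False]
        assert (coding["winstay"] == 0).all()

    def test_all_lost_session_has_no_valid_rows(self):
        trials = make_session(pairs=[(0, 1)] * 4, choices=[None] * 4,
                              outcomes=[None] * 4, lost=[True] * 4)
        assert rl.code_winstay(trials)["valid"].sum() == 0

    def test_cross_block_pairs_excluded(self):
        a = make_session(pairs=[(0, 1)] * 2, choices=[0, 0], outcomes=[1, 1], block=0)
        b = make_session(pairs=[(0, 1)] * 2, choices=[0, 0], outcomes=[1, 1], block=1)
        coding = rl.code_winstay(pd.concat([a, b], ignore_index=True))
        assert len(coding) == 2  # one pair per block, none across

    def test_stickiness_tracks_repeated_choices(self):
        trials = make_session(pairs=[(0, 1), (0, 1), (0, 1)], choices=[0, 0, 1],
                              outcomes=[0, 0, 0])
        coding = rl.code_winstay(trials)
        assert coding["stickiness"].tolist() == [0, 1]  # first block trial gets 0

    def test_model_pe_replaces_reward_regressor(self):
        trials = make_session(pairs=[(0, 1), (0, 1)], choices=[0, 0], outcomes=[1, 1])
        params = rl.AgentParams(model_id="RW1", alpha=0.4, beta=5.0)
        latents = rl.run_model(params, trials)
        coding = rl.code_winstay(trials, latents=latents, source="model_pe")
        assert coding["reward"].iloc[0] == pytest.approx(0.5)  # delta = 1 - 0.5
        with pytest.raises(rl.DataError):
            rl.code_winstay(trials, source="model_pe")


class TestWinstayRegression:
    def test_recovers_constructed_coefficients(self, rng):
        n = 400
        reward = rng.integers(0, 2, n)
        stick = rng.integers(0, 2, n)
        ishp = rng.integers(0, 2, n)
        coding = pd.DataFrame({
            "t": np.arange(n), "block": 0,
            "winstay": reward.astype(float),  # WinStay == Reward exactly
            "reward": reward, "stickiness": stick, "is_hp_next": ishp,
            "valid": True,
        })
        r = rl.winstay_regression(coding)
        assert r.beta_reward == pytest.approx(1.0, abs=1e-8)
        assert r.beta_stickiness == pytest.approx(0.0, abs=1e-8)
        assert r.beta_ishp == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_outcome_gives_zero_coefficients(self, rng):
        n = 50
        coding = pd.DataFrame({
            "t": np.arange(n), "block": 0, "winstay": 0,
            "reward": rng.integers(0, 2, n), "stickiness": rng.integers(0, 2, n),
            "is_hp_next": rng.integers(0, 2, n), "valid": True,
        })
        r = rl.winstay_regression(coding)
        assert (r.beta_reward, r.beta_stickiness, r.beta_ishp) == (0, 0, 0)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        n = 50
        coding = pd.DataFrame({
            "t": np.arange(n), "block": 0,
            "winstay": rng.choice([-1, 0, 1], n),
            "reward": rng.integers(0, 2, n),
            "stickiness": rng.integers(0, 2, n),
            "is_hp_next": rng.integers(0, 2, n),
            "valid": True,
        })
        ours = rl.winstay_regression(coding)
        X = sm.add_constant(coding[["reward", "stickiness", "is_hp_next"]].to_numpy(dtype=float))
        ref = sm.OLS(coding["winstay"].to_numpy(dtype=float), X).fit()
        np.testing.assert_allclose(
            [ours.intercept, ours.beta_reward, ours.beta_stickiness, ours.beta_ishp],
            ref.params, atol=1e-8)

    def test_constant_regressor_warns_not_crashes(self, rng):
        n = 30
        coding = pd.DataFrame({
            "t": np.arange(n), "block": 0,
            "winstay": rng.choice([-1, 0, 1], n),
            "reward": rng.integers(0, 2, n),
            "stickiness": np.ones(n, dtype=int),  # constant
            "is_hp_next": rng.integers(0, 2, n),
            "valid": True,
        })
        with pytest.warns(UserWarning, match="stickiness"):
            r = rl.winstay_regression(coding)
        assert np.isnan(r.beta_stickiness)
        assert np.isfinite(r.beta_reward)

    def test_too_few_rows_raises(self):
        coding = pd.DataFrame({"t": [0], "block": [0], "winstay": [1], "reward": [1],
                               "stickiness": [0], "is_hp_next": [1], "valid": [True]})
        with pytest.raises(rl.DataError):
            rl.winstay_regression(coding)


class TestConditionAnova:
    CONDS = ("NAcc", "dACC", "Sham")

    def test_identical_conditions_give_zero_statistics(self, rng):
        base = _betas_frame(rng, 10, ("X",))
        betas = pd.concat([base.assign(condition=c) for c in self.CONDS], ignore_index=True)
        cmp = rl.condition_anova(betas)
        assert cmp.f_stat == 0.0 and cmp.p_anova == 1.0
        assert all(p.cohens_d == 0.0 and p.t_stat == 0.0 for p in cmp.pairs)

    def test_shifted_condition_detected(self, rng):
        hits = 0
        for _ in range(20):
            betas = _betas_frame(rng, 26, self.CONDS, shift={"NAcc": 1.0}, sd=1.0)
            cmp = rl.condition_anova(betas)
            hits += cmp.p_anova < 0.05
        assert hits >= 16  # +1 SD shift at n=26 is detected reliably

    def test_null_rejection_rate_near_nominal(self, rng):
        # quick check; the full 1000-replicate calibration runs in acceptance
        rejections = sum(
            rl.condition_anova(_betas_frame(rng, 12, self.CONDS)).p_anova < 0.05
            for _ in range(200))
        assert 2 <= rejections <= 22  # wide 3-sigma band around 10/200

    def test_degrees_of_freedom_match_design(self, rng):
        cmp = rl.condition_anova(_betas_frame(rng, 26, self.CONDS))
        assert (cmp.df_between, cmp.df_within) == (2, 75)
        assert all(p.df == 25 for p in cmp.pairs)
        assert all(p.p_bonferroni == min(1.0, 3 * p.p_raw) for p in cmp.pairs)

    def test_subject_missing_condition_dropped_with_warning(self, rng):
        betas = _betas_frame(rng, 6, self.CONDS)
        betas = betas[~((betas["subject"] == "s00") & (betas["condition"] == "Sham"))]
        with pytest.warns(UserWarning, match="s00"):
            cmp = rl.condition_anova(betas)
        assert cmp.n_subjects == 5


class TestBlockwiseContrast:
    def test_identical_conditions_give_zero_t(self, rng):
        base = _betas_frame(rng, 8, ("A",))
        betas = pd.concat([base, base.assign(condition="B")], ignore_index=True)
        out = rl.blockwise_contrast(betas, "A", "B")
        assert (out["t_stat"] == 0.0).all()
        assert not out["significant"].any()

    def test_swapping_conditions_flips_signs(self, rng):
        betas = _betas_frame(rng, 10, ("A", "B"), shift={"A": 0.4})
        ab = rl.blockwise_contrast(betas, "A", "B")
        ba = rl.blockwise_contrast(betas, "B", "A")
        np.testing.assert_allclose(ab["t_stat"], -ba["t_stat"])

    def test_effect_localised_to_injected_blocks(self, rng):
        # expected joint rate ~0.82 (perfect per-block power x ~0.90 chance of
        # both null blocks staying quiet); 40 replicates stabilise the >=70% bar
        hits = 0
        for _ in range(40):
            shift = {("A", 1): 1.5, ("A", 2): 1.5}
            betas = _betas_frame(rng, 26, ("A", "B"), shift=shift)
            out = rl.blockwise_contrast(betas, "A", "B").set_index("block")
            if (out.loc[[1, 2], "significant"].all()
                    and not out.loc[[0, 3], "significant"].any()):
                hits += 1
        assert hits >= 28  # >= 70% of replicates flag exactly the injected blocks

    def test_too_few_subjects_skips_block(self, rng):
        betas = _betas_frame(rng, 2, ("A", "B"), n_blocks=2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = rl.blockwise_contrast(betas, "A", "B")
        assert out.empty


class TestLearningCurve:
    def test_window_one_is_identity(self, default_schedule):
        trials = rl.simulate_agent(
            rl.AgentParams(model_id="RW1", alpha=0.5, beta=8.0), default_schedule, seed=0)
        curve = rl.learning_curve(trials, window=1)
        np.testing.assert_allclose(curve["raw"], curve["smoothed"])

    def test_omniscient_agent_curve_is_one(self, default_schedule):
        t = default_schedule.table
        on_screen = (t["hp_symbol"] == t["sym_left"]) | (t["hp_symbol"] == t["sym_right"])
        trials = pd.DataFrame({
            "subject": "s00", "condition": "none",
            "block": t["block"], "trial": t["trial"],
            "sym_left": t["sym_left"], "sym_right": t["sym_right"],
            "chosen": np.where(on_screen, t["hp_symbol"], t["sym_left"]).astype(float),
            "outcome": 1.0, "lost": False, "hp_symbol": t["hp_symbol"],
        })
        curve = rl.learning_curve(trials, window=1)
        np.testing.assert_allclose(curve["raw"].dropna(), 1.0)

    def test_learner_improves_within_period(self):
        params = rl.AgentParams(model_id="RW1", alpha=0.5, beta=10.0)
        frames = []
        for seed in range(50):
            sched = rl.build_schedule(rl.TaskConfig(block_lengths=(100,), seed=seed))
            frames.append(rl.simulate_agent(params, sched, seed=seed,
                                            subject=f"s{seed:03d}"))
        curve = rl.learning_curve(pd.concat(frames, ignore_index=True), window=1)
        assert curve["raw"].iloc[20:25].mean() > curve["raw"].iloc[0:5].mean()

    def test_smoothing_preserves_range_and_mean(self, default_schedule):
        trials = rl.simulate_agent(
            rl.AgentParams(model_id="RW1", alpha=0.4, beta=6.0), default_schedule, seed=1)
        curve = rl.learning_curve(trials, window=5)
        assert curve["smoothed"].between(0, 1).all()
        assert abs(curve["smoothed"].mean() - curve["raw"].mean()) < 0.02

    def test_model_source_uses_expected_values(self, default_schedule):
        params = rl.AgentParams(model_id="RW1", alpha=0.0, beta=5.0)
        trials = rl.simulate_agent(params, default_schedule, seed=2)
        latents = rl.run_model(params, trials)
        curve = rl.learning_curve(trials, source="model", latents=latents, window=1)
        np.testing.assert_allclose(curve["raw"], 0.5)  # frozen values stay at v0

    def test_oversized_window_raises(self, default_schedule):
        trials = rl.simulate_agent(
            rl.AgentParams(model_id="RW1", alpha=0.4, beta=6.0), default_schedule, seed=3)
        with pytest.raises(rl.ConfigError, match="window"):
            rl.learning_curve(trials, window=26)


class TestHpChoiceMixedModel:
    @staticmethod
    def _cohort(rng, n_subjects, p_by_cond):
        frames = []
        for s in range(n_subjects):
            for cond, p in p_by_cond.items():
                sched = rl.build_schedule(rl.TaskConfig(
                    block_lengths=(60,), seed=int(rng.integers(2 ** 31))))
                t = sched.table
                on = (t["hp_symbol"] == t["sym_left"]) | (t["hp_symbol"] == t["sym_right"])
                pick_hp = rng.random(len(t)) < p
                chosen = np.where(on & pick_hp, t["hp_symbol"],
                                  np.where(t["sym_left"] != t["hp_symbol"],
                                           t["sym_left"], t["sym_right"]))
                frames.append(pd.DataFrame({
                    "subject": f"s{s:02d}", "condition": cond,
                    "block": t["block"], "trial": t["trial"],
                    "sym_left": t["sym_left"], "sym_right": t["sym_right"],
                    "chosen": chosen.astype(float), "outcome": 1.0,
                    "lost": False, "hp_symbol": t["hp_symbol"]}))
        return pd.concat(frames, ignore_index=True)

    def test_balanced_no_subject_variance_matches_ols(self, rng):
        import statsmodels.api as sm
        trials = self._cohort(rng, 6, {"A": 0.6, "B": 0.6})
        res = rl.hp_choice_mixed_model(trials, "A", "B")
        on = (trials["hp_symbol"] == trials["sym_left"]) | \
             (trials["hp_symbol"] == trials["sym_right"])
        df = trials[on]
        y = (df["chosen"] == df["hp_symbol"]).astype(float).to_numpy()
        X = sm.add_constant((df["condition"] == "B").astype(float).to_numpy())
        ols = sm.OLS(y, X).fit()
        assert res.estimate == pytest.approx(float(ols.params[1]), abs=1e-6)

    def test_injected_difference_detected_with_sign(self, rng):
        signs = 0
        for _ in range(5):
            trials = self._cohort(rng, 26, {"A": 0.55, "B": 0.65})
            res = rl.hp_choice_mixed_model(trials, "A", "B")
            signs += res.estimate > 0
        assert signs == 5

    def test_null_effect_rarely_significant(self, rng):
        small = 0
        for _ in range(10):
            trials = self._cohort(rng, 12, {"A": 0.6, "B": 0.6})
            res = rl.hp_choice_mixed_model(trials, "A", "B")
            small += abs(res.t_stat) < 2
        assert small >= 8

    def test_single_subject_falls_back_to_ols(self, rng):
        trials = self._cohort(rng, 1, {"A": 0.6, "B": 0.6})
        with pytest.warns(UserWarning, match="single subject"):
            res = rl.hp_choice_mixed_model(trials, "A", "B")
        assert res.method == "ols"


class TestMaladaptiveWinstay:
    @staticmethod
    def _session(repeat: bool, subject="s00", condition="none"):
        # pair CA (low-low, hp=B) rewarded, then AB offers the same low
        # symbol next to the high-probability one
        return make_session(
            pairs=[(2, 0), (0, 1), (2, 0), (0, 1)],
            choices=[0, 0 if repeat else 1, 0, 0 if repeat else 1],
            outcomes=[1, 0, 1, 0],
            hp=[1, 1, 1, 1],
            subject=subject, condition=condition,
        )

    def test_always_repeat_agent_scores_plus_one(self):
        res = rl.maladaptive_winstay(self._session(True))
        assert res.rates["rate"].tolist() == [1.0]

    def test_never_repeat_agent_scores_minus_one(self):
        res = rl.maladaptive_winstay(self._session(False))
        assert res.rates["rate"].tolist() == [-1.0]

    def test_high_reward_learning_rate_raises_repetition(self):
        lo = rl.AgentParams(model_id="RW2", alpha_pos=0.3, alpha_neg=0.3, beta=5.0)
        hi = rl.AgentParams(model_id="RW2", alpha_pos=0.85, alpha_neg=0.3, beta=5.0)
        rates = {"lo": [], "hi": []}
        for seed in range(100):
            sched = rl.build_schedule(rl.TaskConfig(block_lengths=(100,), seed=seed))
            for name, params in (("lo", lo), ("hi", hi)):
                trials = rl.simulate_agent(params, sched, seed=seed)
                codes = rl.stats._maladaptive_codes(trials)
                if codes:
                    rates[name].append(np.mean(codes))
        assert np.mean(rates["hi"]) > np.mean(rates["lo"])


class TestExploratoryMetrics:
    def test_perfect_tracker_metrics(self, default_schedule):
        t = default_schedule.table
        on = (t["hp_symbol"] == t["sym_left"]) | (t["hp_symbol"] == t["sym_right"])
        trials = pd.DataFrame({
            "subject": "s00", "condition": "none",
            "block": t["block"], "trial": t["trial"],
            "sym_left": t["sym_left"], "sym_right": t["sym_right"],
            "chosen": np.where(on, t["hp_symbol"], t["sym_left"]).astype(float),
            "outcome": 1.0, "lost": False, "hp_symbol": t["hp_symbol"],
        })
        m = rl.exploratory_metrics(trials).iloc[0]
        assert m["post_learning_acc"] == pytest.approx(1.0)
        assert m["perseveration"] == pytest.approx(0.0)

    def test_all_lost_session_reports_missing(self):
        trials = make_session(pairs=[(0, 1)] * 10, choices=[None] * 10,
                              outcomes=[None] * 10, lost=[True] * 10)
        m = rl.exploratory_metrics(trials).iloc[0]
        assert np.isnan(m["post_learning_acc"])
        assert np.isnan(m["perseveration"])
        assert np.isnan(m["post_error_adjustment"])

    def test_value_blind_agent_adjusts_like_baseline(self):
        # with alpha = 0 the outcome cannot influence switching
        params = rl.AgentParams(model_id="RW1", alpha=0.0, beta=5.0)
        diffs = []
        for seed in range(50):
            sched = rl.build_schedule(rl.TaskConfig(block_lengths=(100,), seed=seed))
            trials = rl.simulate_agent(params, sched, seed=seed)
            m = rl.exploratory_metrics(trials).iloc[0]
            diffs.append(m["post_error_adjustment"] - m["overall_switch"])
        assert abs(np.mean(diffs)) < 0.03


class TestRankTest:
    def test_identical_groups(self):
        u, p = rl.rank_test_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n_a * n_b / 2 under mid-ranks
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_groups_exact(self):
        u, p = rl.rank_test_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # 2/C(6,3) enumeration

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=9).tolist()
        b = rng.normal(0.5, size=7).tolist()
        u1, p1 = rl.rank_test_groups(a, b)
        u2, p2 = rl.rank_test_groups(np.exp(a), np.exp(b))
        assert (u1, p1) == (u2, p2)

    def test_empty_group_raises(self):
        with pytest.raises(rl.DataError):
            rl.rank_test_groups([], [1.0])
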