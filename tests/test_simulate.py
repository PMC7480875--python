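"""Synthetic agents, cohorts, bonus rounds, schema round-trips."""

import numpy as np
import pytest
from scipy import stats

import gridbandits as gb
from gridbandits.data import choices_frame, datasets_from_frames, judgments_frame, validate
from gridbandits.simulate import CohortConfig, draw_population_params


def _round_means(ds, from_trial=0):
    return np.array([r.reward[from_trial:].mean() for r in ds.training_rounds()])


class TestSimulateAgent:
    def test_dataset_passes_schema_validation(self, gp_dataset, bmt_dataset):
        validate(gp_dataset)
        validate(bmt_dataset)

    def test_same_seed_is_bit_identical(self, gp_params, smooth_envs):
        a = gb.simulate_agent(gp_params, smooth_envs, seed=5)
        b = gb.simulate_agent(gp_params, smooth_envs, seed=5)
        for ra, rb in zip(a.rounds, b.rounds):
            np.testing.assert_array_equal(ra.chosen, rb.chosen)
            np.testing.assert_array_equal(ra.reward, rb.reward)
        np.testing.assert_array_equal(a.judgments.options, b.judgments.options)

    def test_gp_agent_beats_chance_in_smooth_environments(self, gp_params, smooth_envs):
        # ~500 rounds of GP search vs the analytic chance level
        rewards = np.concatenate([
            _round_means(gb.simulate_agent(gp_params, smooth_envs, seed=100 + i))
            for i in range(55)])
        chance = np.mean([e.means.mean() for e in smooth_envs]) * 87.5
        assert len(rewards) >= 490
        assert rewards.mean() > chance + 2.0

    def test_infinite_temperature_agent_is_chance_level(self, smooth_envs):
        hot = gb.ParamSet(model="gp", lambda_=1.0, beta=0.5, tau=1e6)
        hot_rewards = np.concatenate([
            _round_means(gb.simulate_agent(hot, smooth_envs, seed=200 + i))
            for i in range(28)])
        rand_rewards = np.concatenate([
            _round_means(gb.random_baseline(env_set=smooth_envs, seed=300 + i))
            for i in range(28)])
        t, p = stats.ttest_ind(hot_rewards, rand_rewards)
        assert p > 0.01  # indistinguishable from the uniform policy

    def test_unknown_model_rejected(self, smooth_envs):
        with pytest.raises(ValueError):
            gb.ParamSet(model="q_learning", beta=1.0, tau=0.1)
        with pytest.raises(ValueError):
            gb.simulate_agent(gb.ParamSet(model="gp", lambda_=1.0, beta=0.5, tau=0.1),
                              smooth_envs[:5], seed=0)  # too few environments


class TestBonusRound:
    def test_judged_options_disjoint_from_selections(self, gp_dataset):
        seen = set(gp_dataset.bonus_round().chosen[:15].tolist())
        assert not (seen & set(gp_dataset.judgments.options.tolist()))

    def test_bmt_estimates_identical_for_unobserved(self, bmt_dataset):
        # the mean tracker does not generalize: all unobserved options keep
        # the prior mean, so all 10 judgments coincide
        assert len(set(bmt_dataset.judgments.estimate.tolist())) == 1

    def test_gp_confidence_tracks_low_variance_exactly(self, gp_params, smooth_envs):
        pre, js, post = gb.simulate_bonus_round(gp_params, smooth_envs[0], seed=4)
        from gridbandits.learners import KernelSpec, gp_posterior, normalize_reward
        hist = list(zip(pre.chosen.tolist(), normalize_reward(pre.reward).tolist()))
        belief = gp_posterior(hist, KernelSpec(lambda_=gp_params.lambda_))
        var = belief.post_var[js.options]
        rho = stats.spearmanr(js.confidence, var)[0]
        assert rho == pytest.approx(-1.0)

    def test_forced_choice_structure(self, gp_params, smooth_envs):
        pre, js, post = gb.simulate_bonus_round(gp_params, smooth_envs[1], seed=6)
        assert len(pre.chosen) == 15 and len(post.chosen) == 5
        assert js.forced_choice in set(js.options.tolist())
        assert post.chosen[0] == js.forced_choice


class TestCohort:
    def test_balanced_assignment(self, smooth_envs, rough_envs):
        cohort = gb.generate_cohort(4, seed=0, smooth_envs=smooth_envs,
                                    rough_envs=rough_envs)
        assert len(cohort) == 8  # two tasks per participant
        by_pid = {}
        for ds in cohort:
            by_pid.setdefault(ds.participant_id, []).append(ds)
        classes = [v[0].env_class for v in by_pid.values()]
        assert sorted(classes) == ["rough", "rough", "smooth", "smooth"]
        firsts = [ds.task for ds in cohort if ds.task_order == "first"]
        assert sorted(firsts) == ["conceptual", "conceptual", "spatial", "spatial"]

    def test_conceptual_task_shifts_exploration(self, smooth_envs, rough_envs):
        cohort = gb.generate_cohort(6, seed=1, smooth_envs=smooth_envs,
                                    rough_envs=rough_envs)
        betas = {"spatial": [], "conceptual": []}
        taus = {"spatial": [], "conceptual": []}
        for ds in cohort:
            betas[ds.task].append(ds.params.beta)
            taus[ds.task].append(ds.params.tau)
        assert np.median(betas["conceptual"]) < np.median(betas["spatial"])
        assert np.median(taus["conceptual"]) > np.median(taus["spatial"])

    def test_population_medians_match_configuration(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(0)
        draws = [draw_population_params(cfg, rng) for _ in range(500)]
        assert np.median([p.lambda_ for p in draws]) == pytest.approx(0.75, rel=0.10)
        assert np.median([p.beta for p in draws]) == pytest.approx(0.5, rel=0.10)
        assert np.median([p.tau for p in draws]) == pytest.approx(0.09, rel=0.10)

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValueError):
            gb.generate_cohort(1, seed=0)


class TestRandomBaseline:
    def test_step_distance_matches_brute_force(self, smooth_envs):
        from gridbandits.grid import MANHATTAN
        dists = []
        for i in range(25):
            ds = gb.random_baseline(env_set=smooth_envs, seed=400 + i)
            for r in ds.training_rounds():
                dists.append(MANHATTAN[r.chosen[:-1], r.chosen[1:]])
        dists = np.concatenate(dists).astype(float)
        se = dists.std(ddof=1) / np.sqrt(len(dists))
        assert abs(dists.mean() - 5.25) < 3 * se

    def test_expected_reward_is_mean_surface_times_mean_scale(self, smooth_envs):
        rewards = np.concatenate([
            _round_means(gb.random_baseline(env_set=smooth_envs, seed=500 + i))
            for i in range(30)])
        expected = np.mean([e.means.mean() for e in smooth_envs]) * 87.5
        assert rewards.mean() == pytest.approx(expected, abs=1.0)


class TestSchemaRoundTrip:
    def test_choices_frame_round_trip(self, gp_dataset, bmt_dataset):
        frame = choices_frame([gp_dataset, bmt_dataset])
        assert len(frame) == 2 * 10 * 20
        back = datasets_from_frames(frame, judgments_frame([gp_dataset, bmt_dataset]))
        assert len(back) == 2
        orig = {(d.participant_id, d.task): d for d in (gp_dataset, bmt_dataset)}
        for ds in back:
            ref = orig[(ds.participant_id, ds.task)]
            for ra, rb in zip(ds.rounds, ref.rounds):
                np.testing.assert_array_equal(ra.chosen, rb.chosen)
                np.testing.assert_array_equal(ra.start, rb.start)
                np.testing.assert_allclose(ra.reward, rb.reward)
                assert ra.spec.scale_max == rb.spec.scale_max
            np.testing.assert_array_equal(np.sort(ds.judgments.options),
                                          np.sort(ref.judgments.options))
            validate(ds)

    def test_validator_catches_corruption(self, gp_dataset):
        import dataclasses
        bad = dataclasses.replace(gp_dataset, rounds=gp_dataset.rounds[:9])
        with pytest.raises(ValueError):
            validate(bad)
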