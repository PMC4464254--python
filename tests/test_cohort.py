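"""Synthetic agents, cohort couplings, and BOLD/resting generators."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from riskdeck.cohort import (
    MODULATED_PAIRS,
    ROI_NAMES,
    CohortConfig,
    generate_cohort,
    simulate_model_agent,
    simulate_random_agent,
    simulate_resting_state,
    simulate_task_bold,
    write_cohort,
)
from riskdeck.glm import BlockLayout, build_design, fit_glm
from riskdeck.model import ModelParams, choice_probabilities, deck_moments, trial_modulators
from riskdeck.rsfc import framewise_displacement, scrub_mask
from riskdeck.task import generate_task_sequence


class TestRandomAgent:
    def test_deck_frequencies_uniform(self, task180):
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        n_agents = 50
        for _ in range(n_agents):
            ds = simulate_random_agent(task180, rng)
            counts += np.bincount(ds.choices, minlength=4)
        chi2, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_choices_independent_of_shown_values(self, task180):
        rng = np.random.default_rng(1)
        ds = simulate_random_agent(task180, rng)
        chosen_value = task180.values[np.arange(180), ds.choices]
        ranks = (task180.values < chosen_value[:, None]).sum(axis=1)
        # rank of the chosen deck's value should be ~uniform over 0..3
        assert abs(ranks.mean() - 1.5) < 0.35

    def test_seeded_reproducibility(self, task180):
        a = simulate_random_agent(task180, np.random.default_rng(5))
        b = simulate_random_agent(task180, np.random.default_rng(5))
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.deltas, b.deltas)


class TestModelAgent:
    def test_choice_frequencies_match_softmax(self, task180):
        rng = np.random.default_rng(2)
        l = -0.5
        e, v = deck_moments(task180, 125.0)
        probs = choice_probabilities(e + l * v)
        counts = np.zeros((180, 4))
        n_agents = 400
        for _ in range(n_agents):
            ds = simulate_model_agent(task180, l, rng=rng)
            counts[np.arange(180), ds.choices] += 1
        # per-trial binomial check on the modelled probability of deck A
        k = counts[:, 0]
        pvals = np.array(
            [stats.binomtest(int(ki), n_agents, pi).pvalue for ki, pi in zip(k, probs[:, 0])]
        )
        assert (pvals < 0.001).mean() < 0.03

    def test_extreme_utilities_near_deterministic(self):
        seq = generate_task_sequence(30, rng_seed=3)
        rng = np.random.default_rng(3)
        ds = simulate_model_agent(seq, 1.0, payoff_scale=10.0, rng=rng)
        e, v = deck_moments(seq, 10.0)
        assert (ds.choices == np.argmax(e + 1.0 * v, axis=1)).mean() > 0.9

    def test_rejects_out_of_bounds_preference(self, task180):
        with pytest.raises(ValueError):
            simulate_model_agent(task180, 1.5)


class TestGenerateCohort:
    def test_uncorrelated_config_gives_near_zero_correlation(self, task180):
        cfg = dataclasses.replace(
            CohortConfig(), n_subjects=500, rho_ns_l=1e-9, rng_seed=4
        )
        cohort = generate_cohort(cfg, task180)
        assert abs(cohort.achieved["ns_l"]) < 0.1

    def test_default_coupling_recovered_at_large_n(self, task180):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=500, rng_seed=5)
        cohort = generate_cohort(cfg, task180)
        assert abs(cohort.achieved["ns_l"] - 0.555) < 0.1

    def test_ns_scores_are_integers_in_range(self, task180):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=60, rng_seed=6)
        cohort = generate_cohort(cfg, task180)
        ns = cohort.ns_scores()
        assert np.array_equal(ns, np.round(ns))
        assert ns.min() >= 0 and ns.max() <= 34
        assert all(-1 <= s.l_true <= 1 for s in cohort.subjects)

    def test_serialisation_roundtrip(self, task180, tmp_path):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=2, rng_seed=7)
        cohort = generate_cohort(cfg, task180)
        write_cohort(cohort, tmp_path)
        assert (tmp_path / "subjects.csv").exists()
        sub = cohort.subjects[0].subject_id
        for f in ("choices.csv", "task_bold.csv", "rest_bold.csv", "motion.csv"):
            assert (tmp_path / sub / f).exists()


class TestTaskBold:
    def test_noiseless_series_recovers_betas_exactly(self, task180):
        rng = np.random.default_rng(8)
        ds = simulate_model_agent(task180, -0.2, rng=rng)
        mods = trial_modulators(task180, ModelParams(-0.2), ds.choices)
        betas = {"risk": 0.7, "reward": -0.4, "entropy": 0.2}
        series = simulate_task_bold(mods, betas, noise_sd=0.0, rng=rng)
        res = fit_glm(series, build_design(mods))
        for name, b in betas.items():
            assert res.coef(name)["beta"] == pytest.approx(b, abs=1e-8)

    def test_series_length_is_three_runs_of_210_volumes(self, task180):
        rng = np.random.default_rng(9)
        ds = simulate_model_agent(task180, 0.0, rng=rng)
        mods = trial_modulators(task180, ModelParams(0.0), ds.choices)
        series = simulate_task_bold(mods, {"risk": 1.0}, rng=rng)
        assert len(series) == 3 * 210
        assert BlockLayout().run_duration == 420.0  # 7-minute runs

    def test_neural_effect_recovered_across_cohort(self, task180):
        # corr(beta_hat_risk, NS) approaches the generating target at large n
        cfg = dataclasses.replace(CohortConfig(), n_subjects=150, rng_seed=10)
        cohort = generate_cohort(cfg, task180)
        ns = cohort.ns_scores()
        design_cache = {}
        betas = []
        for s in cohort.subjects:
            mods = trial_modulators(
                task180, ModelParams(s.l_true, 125.0), s.dataset.choices
            )
            design = build_design(mods)
            res = fit_glm(s.roi_task_series[ROI_NAMES[0]], design)
            betas.append(res.coef("risk")["beta"])
        r = np.corrcoef(ns, betas)[0, 1]
        assert abs(r - cfg.neural_effect) < 0.15


class TestRestingState:
    def test_identity_target_gives_small_off_diagonal(self):
        series, _ = simulate_resting_state(np.eye(4), rng=np.random.default_rng(11))
        C = np.corrcoef(series.T)
        off = C[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_scheduled_spikes_are_exactly_the_scrubbed_volumes(self):
        series, motion = simulate_resting_state(
            np.eye(4),
            spike_schedule=[50, 120],
            spike_magnitudes=[0.8, 0.9],
            rng=np.random.default_rng(12),
        )
        fd = framewise_displacement(motion)
        keep = scrub_mask(fd)
        # a one-volume excursion at k trips FD at k and k+1
        assert set(np.flatnonzero(~keep)) == {50, 51, 120, 121}

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            simulate_resting_state(bad, rng=np.random.default_rng(13))

    def test_modulated_pair_target_tracks_ns(self, task180):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=200, rng_seed=14)
        cohort = generate_cohort(cfg, task180)
        names = list(ROI_NAMES)
        ia, ib = names.index(MODULATED_PAIRS[0][0]), names.index(MODULATED_PAIRS[0][1])
        targets = [s.rest_target[ia, ib] for s in cohort.subjects]
        r = np.corrcoef(cohort.ns_scores(), targets)[0, 1]
        assert r < -0.3  # clipping attenuates the -0.511 latent coupling
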