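import numpy as np
import pytest
from scipy import stats

import headingbias as hb
from headingbias import discrimination as dsc
from headingbias.errors import EstimationError, NonIdentifiableError


class TestStaircaseUpdate:
    def test_1u1d_steps_every_response(self):
        rule = dsc.RULE_1U1D
        assert dsc.staircase_update(rule, 10.0, [True]) == 6.0  # "greater" -> down
        assert dsc.staircase_update(rule, 10.0, [False]) == 14.0  # "less" -> up

    def test_2u1d_needs_a_pair_to_go_up(self):
        rule = dsc.RULE_2U1D
        assert dsc.staircase_update(rule, 0.0, [False]) == 0.0
        assert dsc.staircase_update(rule, 0.0, [False, False]) == 4.0
        assert dsc.staircase_update(rule, 0.0, [True]) == -4.0

    def test_1u2d_needs_a_pair_to_go_down(self):
        rule = dsc.RULE_1U2D
        assert dsc.staircase_update(rule, 0.0, [True]) == 0.0
        assert dsc.staircase_update(rule, 0.0, [True, True]) == -4.0
        assert dsc.staircase_update(rule, 0.0, [False]) == 4.0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            dsc.staircase_update(dsc.RULE_1U1D, 0.0, [])

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            dsc.StaircaseRule(3, 1)
        with pytest.raises(ValueError):
            dsc.StaircaseRule(1, 1, step_deg=0.0)


class TestRunBlock:
    def test_same_seed_identical_blocks(self):
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        a = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=3)
        b = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=3)
        assert a.trials.equals(b.trials)

    def test_trial_count_and_interleaving(self):
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=0)
        assert len(blk.trials) == 70
        # strict alternation of the two tracks
        assert list(blk.trials["staircase_id"][:4]) == [0, 1, 0, 1]

    def test_near_deterministic_observer_descends_then_oscillates(self):
        obs = hb.Simulated2AFCObserver(0.0, 1e-9)
        blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=0)
        desc = blk.trials[blk.trials["staircase_id"] == 0]
        levels = desc["stimulus_deg"].to_numpy()
        # strictly monotone 4-deg descent from +26 until crossing the PSE
        n_desc = int(np.ceil(26.0 / 4.0))
        np.testing.assert_allclose(np.diff(levels[: n_desc + 1]), -4.0)
        # afterwards: oscillation with one-step amplitude around the PSE
        tail = levels[n_desc + 1 :]
        assert np.ptp(tail) <= 4.0
        assert np.all(np.abs(tail) <= 4.0)

    def test_final_levels_converge_near_pse(self):
        """1U1D staircases end within +/-2 steps of the PSE in >=90% of runs."""
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        hits = total = 0
        for seed in range(200):
            blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=seed)
            final = blk.trials.groupby("staircase_id")["stimulus_deg"].last()
            hits += int((final.abs() <= 8.0).sum())
            total += 2
        assert hits / total >= 0.9

    def test_too_few_trials_rejected(self):
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        with pytest.raises(ValueError):
            dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 5, 26.0, seed=0)


class TestPseFromReversals:
    def test_mean_of_late_reversals(self):
        import pandas as pd

        revs = [10.0, -2.0, 2.0, -2.0, 2.0, -2.0, 2.0]
        expected = float(np.mean(revs[4:]))  # direct arithmetic oracle
        trials = pd.DataFrame(
            {
                "trial": np.arange(1, len(revs) + 1),
                "staircase_id": 0,
                "stimulus_deg": revs,
                "response_cw": 0,
                "is_reversal": 1,
            }
        )
        blk = dsc.StaircaseBlock(0.0, dsc.RULE_1U1D, len(revs), 26.0, trials)
        assert dsc.pse_from_reversals(blk) == pytest.approx(expected)

    def test_symmetric_oscillation_estimates_zero(self):
        obs = hb.Simulated2AFCObserver(0.0, 1e-9)
        blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=0)
        assert abs(dsc.pse_from_reversals(blk)) <= 2.0  # half a step

    def test_monte_carlo_mean_recovers_pse(self):
        obs = hb.Simulated2AFCObserver(-90.0, 8.0)
        ests = [
            dsc.pse_from_reversals(
                dsc.run_block(obs, -90.0, dsc.RULE_1U1D, 35, 26.0, seed=s)
            )
            for s in range(500)
        ]
        assert np.mean(ests) == pytest.approx(-90.0, abs=1.0)

    def test_too_few_reversals_raises_with_count(self):
        obs = hb.Simulated2AFCObserver(0.0, 1e-9)
        # monotone descent from far away: no reversals in 10 trials
        blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 10, 80.0, seed=0)
        with pytest.raises(EstimationError) as err:
            dsc.pse_from_reversals(blk)
        assert "n_reversals" in err.value.context


class TestFitCumulativeGaussian:
    def test_exact_proportions_recover_parameters(self):
        pse, jnd = -75.0, 8.42
        levels = np.array([-95.0, -85.0, -75.0, -65.0, -55.0])
        n = np.full(levels.size, 1000.0)
        n_cw = n * stats.norm.cdf((levels - pse) / jnd)
        fit = dsc.fit_cumulative_gaussian(levels, n_cw, n)
        assert fit.pse_deg == pytest.approx(pse, abs=1e-4)
        assert fit.jnd_deg == pytest.approx(jnd, abs=1e-4)

    def test_matches_probit_glm(self):
        """Cross-check the in-house MLE against a probit GLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        levels = np.arange(-20.0, 21.0, 4.0)
        n = np.full(levels.size, 40.0)
        n_cw = rng.binomial(40, stats.norm.cdf((levels - 2.0) / 7.0)).astype(float)
        fit = dsc.fit_cumulative_gaussian(levels, n_cw, n)
        glm = sm.GLM(
            np.column_stack([n_cw, n - n_cw]),
            sm.add_constant(levels),
            family=sm.families.Binomial(link=sm.families.links.Probit()),
        ).fit()
        b0, b1 = glm.params
        assert fit.pse_deg == pytest.approx(-b0 / b1, abs=1e-3)
        assert fit.jnd_deg == pytest.approx(1.0 / b1, rel=1e-3)

    def test_mirrored_data_negates_pse_preserves_jnd(self):
        levels = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        n = np.full(5, 200.0)
        n_cw = n * stats.norm.cdf((levels - 2.0) / 6.0)
        f = dsc.fit_cumulative_gaussian(levels, n_cw, n)
        g = dsc.fit_cumulative_gaussian(-levels, n - n_cw, n)
        assert g.pse_deg == pytest.approx(-f.pse_deg, abs=1e-6)
        assert g.jnd_deg == pytest.approx(f.jnd_deg, rel=1e-6)

    def test_staircase_scenario_recovery(self):
        """PSE -75 / JND 8.42 scenario: mean recovered parameters across
        seeded staircase sessions land close to the generating values."""
        obs = hb.Simulated2AFCObserver(-75.0, 8.42)
        pses, jnds = [], []
        for seed in range(200):
            blocks = [
                dsc.run_block(obs, -75.0, dsc.RULE_1U1D, 35, 26.0, seed=3 * seed),
                dsc.run_block(obs, -75.0, dsc.RULE_2U1D, 20, 18.0, seed=3 * seed + 1),
                dsc.run_block(obs, -75.0, dsc.RULE_1U2D, 20, 18.0, seed=3 * seed + 2),
            ]
            import pandas as pd

            trials = pd.concat([b.trials for b in blocks])
            g = trials.groupby("stimulus_deg")["response_cw"].agg(["sum", "count"])
            fit = dsc.fit_cumulative_gaussian(
                g.index.to_numpy(), g["sum"].to_numpy(), g["count"].to_numpy()
            )
            pses.append(fit.pse_deg)
            jnds.append(fit.jnd_deg)
        assert np.mean(pses) == pytest.approx(-75.0, abs=2.0)
        assert np.mean(jnds) == pytest.approx(8.42, abs=2.0)

    def test_one_category_rejected(self):
        levels = np.array([0.0, 4.0, 8.0])
        with pytest.raises(NonIdentifiableError):
            dsc.fit_cumulative_gaussian(levels, np.zeros(3), np.full(3, 10.0))

    def test_degenerate_levels_rejected(self):
        with pytest.raises(NonIdentifiableError):
            dsc.fit_cumulative_gaussian(
                np.array([1.0, 1.0, 1.0]), np.array([1.0, 5.0, 9.0]),
                np.full(3, 10.0),
            )


class TestDiscriminationBias:
    @pytest.mark.parametrize(
        "investigated, pse, expected",
        [(-90.0, -75.0, -15.0), (45.0, 45.0, 0.0), (180.0, -175.0, -5.0)],
    )
    def test_wrapped_signed_bias(self, investigated, pse, expected):
        assert hb.discrimination_bias(investigated, pse) == pytest.approx(expected)


class TestConvergencePoints:
    @pytest.mark.parametrize(
        "rule, n_trials, target_p",
        [
            (dsc.RULE_1U1D, 35, 0.5),
            (dsc.RULE_2U1D, 40, 1.0 - np.sqrt(0.5)),
            (dsc.RULE_1U2D, 40, np.sqrt(0.5)),
        ],
    )
    def test_tracked_probability_level(self, rule, n_trials, target_p):
        """Transformed up-down rules track the 50% / 29.3% / 70.7% points."""
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        ests = [
            dsc.pse_from_reversals(
                dsc.run_block(obs, 0.0, rule, n_trials, 18.0, seed=s)
            )
            for s in range(500)
        ]
        tracked = stats.norm.cdf(np.mean(ests) / 8.0)
        assert tracked == pytest.approx(target_p, abs=0.03)

    def test_reversal_and_psychometric_pse_agree(self):
        obs = hb.Simulated2AFCObserver(0.0, 8.0)
        diffs = []
        for seed in range(100):
            blk = dsc.run_block(obs, 0.0, dsc.RULE_1U1D, 35, 26.0, seed=seed)
            rev = dsc.pse_from_reversals(blk)
            g = blk.trials.groupby("stimulus_deg")["response_cw"].agg(
                ["sum", "count"]
            )
            fit = dsc.fit_cumulative_gaussian(
                g.index.to_numpy(), g["sum"].to_numpy(), g["count"].to_numpy()
            )
            diffs.append(rev - fit.pse_deg)
        assert abs(np.mean(diffs)) < 1.0
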