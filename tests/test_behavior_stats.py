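import numpy as np
import pandas as pd
import pytest

from twostage.agents import AgentParams, simulate_agent
from twostage.behavior_stats import (
    COND1_TERMS,
    COND2_TERMS,
    build_choice_gaze_design,
    build_stay_design,
    fit_choice_regression,
    fit_stay_regression,
    stay_probability_table,
)
from twostage.task_engine import TaskConfig


def _trials_frame(rows, condition=1):
    defaults = {
        "subject_id": "s0",
        "condition": condition,
        "colour_dev_A": 0.0,
        "colour_dev_B": 0.0,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update({"trial": i})
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestBuildStayDesign:
    def test_first_trial_dropped(self):
        trials = _trials_frame(
            [
                {"a1": "A", "transition_type": "common", "reward": 1},
                {"a1": "A", "transition_type": "rare", "reward": 0},
            ]
        )
        design = build_stay_design(trials, condition=1)
        assert len(design) == 1
        assert design.iloc[0]["trial"] == 1

    def test_stay_and_previous_trial_coding(self):
        trials = _trials_frame(
            [
                {"a1": "A", "transition_type": "common", "reward": 1},
                {"a1": "A", "transition_type": "rare", "reward": 0},
                {"a1": "B", "transition_type": "common", "reward": 1},
            ]
        )
        design = build_stay_design(trials, condition=1)
        assert list(design["stay"]) == [1, 0]
        assert list(design["reward"]) == [1, 0]  # previous-trial reward
        assert list(design["transition"]) == [1, 0]

    def test_always_repeat_agent(self):
        trials = _trials_frame(
            [{"a1": "A", "transition_type": "common", "reward": 1}] * 10
        )
        design = build_stay_design(trials, condition=1)
        assert (design["stay"] == 1).all()

    def test_colour_diff_from_quoted_definition(self):
        # A chosen at t-1 (common blue); blue share A=+0.2, blue share B=-0.1.
        # Stored per-symbol devs are for each symbol's own common colour, so
        # dev_A=+0.2 and dev_B=+0.1 -> colour = 0.2 - (-0.1) = 0.3
        trials = _trials_frame(
            [
                {"a1": "A", "transition_type": "common", "reward": 1},
                {
                    "a1": "A",
                    "transition_type": "common",
                    "reward": 1,
                    "colour_dev_A": 0.2,
                    "colour_dev_B": 0.1,
                },
            ],
            condition=2,
        )
        design = build_stay_design(trials, condition=2)
        assert design.iloc[0]["colour"] == pytest.approx(0.3)

    def test_condition1_design_is_nested_in_condition2(self):
        assert COND2_TERMS[: len(COND1_TERMS)] == COND1_TERMS
        assert all("colour" in t for t in COND2_TERMS[len(COND1_TERMS):])


class TestStayProbabilityTable:
    def test_deterministic_stay(self):
        rows = pd.DataFrame(
            {
                "subject_id": ["s0"] * 4,
                "stay": [1, 1, 1, 1],
                "reward": [0, 0, 1, 1],
                "transition": [0, 1, 0, 1],
            }
        )
        table = stay_probability_table(rows)
        assert (table["p_stay"] == 1.0).all()

    def test_missing_cell_flagged(self):
        rows = pd.DataFrame(
            {
                "subject_id": ["s0", "s0"],
                "stay": [1, 0],
                "reward": [1, 1],
                "transition": [1, 1],
            }
        )
        table = stay_probability_table(rows).set_index(["reward", "transition"])
        assert np.isnan(table.loc[(0, 0), "p_stay"])
        assert table.loc[(0, 0), "n_subjects"] == 0
        assert table.loc[(1, 1), "p_stay"] == pytest.approx(0.5)

    def test_subject_first_aggregation(self):
        # s0 contributes many rows, s1 few: cell mean is the mean of the
        # two subject means, not the pooled mean
        rows = pd.DataFrame(
            {
                "subject_id": ["s0"] * 8 + ["s1"] * 2,
                "stay": [1] * 8 + [0] * 2,
                "reward": [1] * 10,
                "transition": [1] * 10,
            }
        )
        table = stay_probability_table(rows).set_index(["reward", "transition"])
        assert table.loc[(1, 1), "p_stay"] == pytest.approx(0.5)


def _simulate_group(w, n_subjects, seed0, n_trials=150, p_stick=0.0):
    frames = []
    for i in range(n_subjects):
        p = AgentParams(alpha=0.7, beta=8.0, lam=0.6, p_stick=p_stick, w=w)
        cfg = TaskConfig(n_trials=n_trials, condition=1, seed=seed0 + i)
        trials, _ = simulate_agent(p, cfg, rng=np.random.default_rng(seed0 + i))
        frames.append(trials.assign(subject_id=f"s{i}"))
    return pd.concat(frames, ignore_index=True)


class TestFitStayRegression:
    def test_null_generator_flat(self, rng):
        rows = []
        for s in range(12):
            stay = rng.integers(0, 2, size=120)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": f"s{s}",
                        "stay": stay,
                        "reward": rng.integers(0, 2, size=120),
                        "transition": rng.integers(0, 2, size=120),
                    }
                )
            )
        res = fit_stay_regression(pd.concat(rows, ignore_index=True))
        assert (res.table["pvalue"] > 0.01).all()

    def test_known_reward_effect_recovered(self, rng):
        # logistic generator: stay ~ sigmoid(1.5 * reward - 0.5)
        rows = []
        for s in range(15):
            reward = rng.integers(0, 2, size=140)
            transition = rng.integers(0, 2, size=140)
            p = 1 / (1 + np.exp(-(1.5 * reward - 0.5)))
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": f"s{s}",
                        "stay": (rng.random(140) < p).astype(int),
                        "reward": reward,
                        "transition": transition,
                    }
                )
            )
        res = fit_stay_regression(pd.concat(rows, ignore_index=True))
        table = res.table.set_index("term")
        assert table.loc["reward", "pvalue"] < 0.05
        assert table.loc["reward", "mean"] > 0
        # slope recovery within 20%
        assert table.loc["reward", "mean"] == pytest.approx(1.5, rel=0.2)
        assert table.loc["reward:transition", "pvalue"] > 0.05

    def test_model_free_agents_reward_main_effect(self):
        trials = _simulate_group(w=0.0, n_subjects=12, seed0=300)
        res = fit_stay_regression(build_stay_design(trials, condition=1))
        table = res.table.set_index("term")
        assert table.loc["reward", "mean"] > 0
        assert table.loc["reward", "pvalue"] < 0.05

    def test_separation_flagged(self):
        rows = pd.DataFrame(
            {
                "subject_id": "s0",
                "stay": [1] * 20 + [0] * 20,
                "reward": [1] * 20 + [0] * 20,
                "transition": [0, 1] * 20,
            }
        )
        with pytest.warns(UserWarning):
            res = fit_stay_regression(rows)
        assert res.n_subjects == 0 or np.isnan(res.per_subject["reward"]).all()


class TestChoiceGazeDesign:
    def _inputs(self):
        trials = _trials_frame(
            [
                {"a1": "A", "transition_type": "common", "reward": 1},
                {"a1": "A", "transition_type": "common", "reward": 1},
                {"a1": "B", "transition_type": "rare", "reward": 0},
                {"a1": "A", "transition_type": "common", "reward": 1},
            ]
        )
        gaze = pd.DataFrame(
            {
                "subject_id": "s0",
                "trial": [0, 1, 2, 3],
                "n_gazes": [1, 2, 2, 3],
                "unique_symbols_viewed": [1, 2, 2, 2],
                "first_symbol": ["A", "B", "B", "A"],
                "last_symbol": ["A", "A", "B", "B"],
                "last_dwell": [200.0, 300.0, 250.0, 400.0],
            }
        )
        qtraj = pd.DataFrame(
            {
                "subject_id": "s0",
                "trial": [0, 1, 2, 3],
                "qA_hybrid": [0.0, 0.5, 0.2, 0.6],
                "qB_hybrid": [0.0, 0.3, 0.5, 0.1],
            }
        )
        return trials, gaze, qtraj

    def test_encoding(self):
        trials, gaze, qtraj = self._inputs()
        design = build_choice_gaze_design(
            trials, gaze, qtraj, group_values={"s0": 1.0}
        )
        # trial 1: gazes [B, A], A chosen
        row = design[design["trial"] == 1].iloc[0]
        assert row["first_gaze_B"] == 1
        assert row["last_gaze_B"] == 0
        assert row["chose_B"] == 0
        assert row["qdiff"] == pytest.approx(-0.2)
        assert row["prev_B"] == 0

    def test_two_or_more_filter(self):
        trials, gaze, qtraj = self._inputs()
        design = build_choice_gaze_design(trials, gaze, qtraj, {"s0": 0.0})
        assert 0 not in set(design["trial"])  # single-gaze trial dropped

    def test_exactly_two_filter(self):
        trials, gaze, qtraj = self._inputs()
        design = build_choice_gaze_design(
            trials, gaze, qtraj, {"s0": 0.0}, gaze_filter="exactly_two"
        )
        assert set(design["trial"]) == {1, 2}

    def test_excluded_trials_absent(self):
        trials, gaze, qtraj = self._inputs()
        gaze = gaze[gaze["trial"] != 2]  # dropped by the gaze pipeline
        design = build_choice_gaze_design(trials, gaze, qtraj, {"s0": 0.0})
        assert 2 not in set(design["trial"])

    def test_bad_filter_rejected(self):
        trials, gaze, qtraj = self._inputs()
        with pytest.raises(ValueError):
            build_choice_gaze_design(trials, gaze, qtraj, {"s0": 0.0}, gaze_filter="x")


class TestFitChoiceRegression:
    def test_recovers_gaze_effects(self, rng):
        # simulated logistic generator with last-gaze and dwell effects
        rows = []
        for s in range(25):
            n = 140
            qdiff = rng.normal(0, 0.4, size=n)
            last_B = rng.integers(0, 2, size=n)
            first_B = rng.integers(0, 2, size=n)
            dwell = rng.normal(0, 1, size=n)
            prev_B = rng.integers(0, 2, size=n)
            logit = 2.0 * qdiff + 1.2 * last_B - 0.6 + 0.5 * dwell * last_B
            p = 1 / (1 + np.exp(-logit))
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": f"s{s}",
                        "trial": np.arange(n),
                        "chose_B": (rng.random(n) < p).astype(int),
                        "qdiff": qdiff,
                        "prev_B": prev_B,
                        "first_gaze_B": first_B,
                        "last_gaze_B": last_B,
                        "last_dwell_z": dwell,
                        "group": float(s % 2),
                    }
                )
            )
        design = pd.concat(rows, ignore_index=True)
        table = fit_choice_regression(
            design, terms=["qdiff", "prev_B", "last_gaze_B", "last_dwell_z:last_gaze_B"]
        ).set_index("term")
        assert table.loc["qdiff", "coef"] == pytest.approx(2.0, rel=0.2)
        assert table.loc["last_gaze_B", "coef"] == pytest.approx(1.2, rel=0.25)
        assert table.loc["last_gaze_B", "pvalue"] < 0.001
        assert table.loc["last_dwell_z:last_gaze_B", "coef"] > 0
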