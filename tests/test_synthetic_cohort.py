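import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from metacheck.synthetic_cohort import (
    AccuracyModel,
    CheckingPolicy,
    CohortConfig,
    Instrument,
    SubjectProfile,
    TrialRecord,
    make_glmm_cohort,
    sample_questionnaires,
    simulate_accuracy,
    simulate_checking_counts,
    simulate_implicit_pair,
    simulate_observer_trial,
    trials_to_frame,
    write_cohort,
)


class TestTypes:
    def test_profile_validation(self):
        with pytest.raises(ValueError):
            SubjectProfile("s", sensitivity_k=-1.0, meta_noise_sigma=0.1)
        with pytest.raises(ValueError):
            SubjectProfile("s", sensitivity_k=1.0, meta_noise_sigma=-0.1)
        with pytest.raises(ValueError, match="increasing"):
            SubjectProfile(
                "s", sensitivity_k=1.0, meta_noise_sigma=0.1,
                confidence_thresholds=(1.0, 0.5, 1.5, 2.0, 2.5),
            )

    def test_trial_record_validation(self):
        with pytest.raises(ValueError, match="task"):
            TrialRecord("s", "bogus", 0.5, 0.0, 1, 1, 1)
        with pytest.raises(ValueError, match="coherence"):
            TrialRecord("s", "checking", 1.5, 0.0, 1, 1, 1)
        with pytest.raises(ValueError, match="inconsistent"):
            TrialRecord("s", "checking", 0.5, 0.0, 1, -1, 1)

    def test_cohort_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CheckingPolicy(subject_sd=-0.1)
        with pytest.raises(ValueError):
            Instrument(mean=10, sd=-1, lower=0, upper=20)


class TestObserverTrial:
    def test_zero_coherence_is_chance(self, profile):
        rng = np.random.default_rng(0)
        correct = [
            simulate_observer_trial(profile, 0.0, "checking", rng).correct
            for _ in range(4000)
        ]
        assert abs(np.mean(correct) - 0.5) < 0.025

    def test_rejects_bad_inputs(self, profile, rng):
        with pytest.raises(ValueError):
            simulate_observer_trial(profile, -0.1, "checking", rng)
        with pytest.raises(ValueError):
            simulate_observer_trial(profile, 0.5, "nope", rng)

    def test_calibration_target_accuracy(self):
        # sensitivity chosen so Phi(k*c) = 0.7 at the target coherence
        c_target = 0.3
        k = ndtri(0.7) / c_target
        prof = SubjectProfile("s", sensitivity_k=k, meta_noise_sigma=0.0)
        rng = np.random.default_rng(1)
        correct = [
            simulate_observer_trial(prof, c_target, "checking", rng).correct
            for _ in range(20000)
        ]
        assert np.mean(correct) == pytest.approx(0.7, abs=0.012)

    def test_accuracy_matches_probit_curve(self, profile):
        # empirical accuracy tracks Phi(k*c) within binomial error
        rng = np.random.default_rng(2)
        n = 20000
        for c in (0.1, 0.3, 0.6):
            correct = [
                simulate_observer_trial(profile, c, "checking", rng).correct
                for _ in range(n)
            ]
            expected = ndtr(profile.sensitivity_k * c)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(np.mean(correct) - expected) < 4 * se

    def test_explicit_confidence_range(self, profile, rng):
        trials = [
            simulate_observer_trial(profile, 0.4, "explicit", rng) for _ in range(500)
        ]
        conf = {t.confidence for t in trials}
        assert conf <= set(range(1, 7))
        assert len(conf) > 1


class TestImplicitPair:
    def test_exactly_one_chosen(self, profile, rng):
        a, b = simulate_implicit_pair(profile, 0.2, 0.4, rng, pair_id=3)
        assert a.pair_id == b.pair_id == 3
        assert a.chosen != b.chosen

    def test_random_chooser_no_accuracy_gap(self, profile):
        rng = np.random.default_rng(3)
        accs = {True: [], False: []}
        for j in range(8000):
            a, b = simulate_implicit_pair(
                profile, 0.3, 0.3, rng, pair_id=j, choice_noise=np.inf
            )
            for t in (a, b):
                accs[t.chosen].append(t.correct)
        assert abs(np.mean(accs[True]) - np.mean(accs[False])) < 0.03

    def test_noiseless_chooser_equal_coherence_gap(self, profile):
        # Monte-Carlo oracle on |evidence| ordering: chosen beats discarded
        rng = np.random.default_rng(4)
        accs = {True: [], False: []}
        for j in range(8000):
            a, b = simulate_implicit_pair(profile, 0.3, 0.3, rng, pair_id=j)
            for t in (a, b):
                accs[t.chosen].append(t.correct)
        assert np.mean(accs[True]) > np.mean(accs[False]) + 0.05


class TestCheckingCounts:
    def design(self, n=5000, n_subj=10, rng=None):
        rng = rng or np.random.default_rng(5)
        return pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(n_subj)], n // n_subj),
                "difficulty": rng.normal(size=n),
                "m_ratio": 0.0, "cmi": 0.0, "padua": 0.0, "mistrust": 0.0,
            }
        )

    def test_homogeneous_poisson_mean(self):
        policy = CheckingPolicy(
            intercept=-0.5, difficulty=0.0,
            trait_by_difficulty={t: 0.0 for t in ("m_ratio", "cmi", "padua", "mistrust")},
            subject_sd=0.0, olre_sd=0.0,
        )
        out = simulate_checking_counts(policy, self.design(n=50000), np.random.default_rng(6))
        assert out["n_checks"].mean() == pytest.approx(np.exp(-0.5), rel=0.03)

    def test_lognormal_poisson_closed_form(self):
        # marginal mean = exp(b0 + (tau^2 + sigma^2)/2) for slope-free policy
        tau, sig = 0.4, 0.5
        policy = CheckingPolicy(
            intercept=-0.3, difficulty=0.0,
            trait_by_difficulty={t: 0.0 for t in ("m_ratio", "cmi", "padua", "mistrust")},
            subject_sd=tau, olre_sd=sig,
        )
        design = self.design(n=100000, n_subj=10000)
        out = simulate_checking_counts(policy, design, np.random.default_rng(7))
        expected = np.exp(-0.3 + (tau**2 + sig**2) / 2)
        assert out["n_checks"].mean() == pytest.approx(expected, rel=0.02)

    def test_counts_increase_with_difficulty(self):
        out = simulate_checking_counts(
            CheckingPolicy(), self.design(n=30000), np.random.default_rng(8)
        )
        terc = pd.qcut(out["difficulty"], 3, labels=[0, 1, 2])
        means = out.groupby(terc, observed=True)["n_checks"].mean()
        assert means[0] < means[1] < means[2]

    def test_nonfinite_eta_names_coefficients(self):
        policy = CheckingPolicy(intercept=np.inf)
        with pytest.raises(ValueError, match="intercept"):
            simulate_checking_counts(policy, self.design(n=100), np.random.default_rng(9))


class TestAccuracy:
    def test_null_model_is_chance(self):
        model = AccuracyModel(
            intercept=0.0, difficulty=0.0, checks=0.0, checks_by_difficulty=0.0,
            subject_sd=0.0,
        )
        df = pd.DataFrame(
            {
                "subject_id": "s0",
                "difficulty": np.random.default_rng(10).normal(size=20000),
                "m_ratio": 0.0, "cmi": 0.0, "padua": 0.0, "mistrust": 0.0,
                "n_checks": np.random.default_rng(11).poisson(0.6, size=20000),
            }
        )
        out = simulate_accuracy(model, df, np.random.default_rng(12))
        assert out["correct"].mean() == pytest.approx(0.5, abs=0.02)

    def test_missing_checks_rejected(self):
        df = pd.DataFrame({"subject_id": ["a"], "difficulty": [0.0]})
        with pytest.raises(ValueError, match="n_checks"):
            simulate_accuracy(AccuracyModel(), df, np.random.default_rng(0))

    def test_checking_penalty_shrinks_with_difficulty(self):
        # checks slope -0.26, interaction +0.20: accuracy drop after checking
        # is larger on easy (low-difficulty) than hard trials
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "subject_id": "s0",
                "difficulty": rng.normal(size=200000),
                "m_ratio": 0.0, "cmi": 0.0, "padua": 0.0, "mistrust": 0.0,
            }
        )
        df["n_checks"] = rng.poisson(0.6, size=len(df))
        out = simulate_accuracy(AccuracyModel(subject_sd=0.0), df, rng)
        easy = out[out["difficulty"] < -0.5]
        hard = out[out["difficulty"] > 0.5]

        def drop(sub):
            return (
                sub.loc[sub["n_checks"] == 0, "correct"].mean()
                - sub.loc[sub["n_checks"] >= 1, "correct"].mean()
            )

        assert drop(easy) > drop(hard)

    def test_glm_oracle_recovers_slopes(self):
        # single subject, zero random variance: statsmodels GLM is the oracle
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(14)
        n = 10000
        df = pd.DataFrame(
            {
                "subject_id": "s0",
                "difficulty": rng.normal(size=n),
                "m_ratio": 0.0, "cmi": 0.0, "padua": 0.0, "mistrust": 0.0,
                "n_checks": rng.poisson(0.6, size=n),
            }
        )
        model = AccuracyModel(subject_sd=0.0)
        out = simulate_accuracy(model, df, rng)
        checks_z = (out["n_checks"] - out["n_checks"].mean()) / out["n_checks"].std(ddof=0)
        X = sm.add_constant(
            np.column_stack([out["difficulty"], checks_z, checks_z * out["difficulty"]]),
            prepend=True,
        )
        res = sm.GLM(out["correct"], X, family=sm.families.Binomial()).fit()
        truth = [model.intercept, model.difficulty, model.checks, model.checks_by_difficulty]
        ci = np.asarray(res.conf_int())
        for i, t in enumerate(truth):
            assert ci[i, 0] - 0.02 <= t <= ci[i, 1] + 0.02


class TestQuestionnaires:
    def test_padua_moments(self):
        inst = {"padua": Instrument(57.6, 28.8, 0, 240)}
        scores = sample_questionnaires(inst, 10000, np.random.default_rng(15))
        assert scores["padua"].mean() == pytest.approx(57.6, abs=0.6)
        assert scores["padua"].std(ddof=1) == pytest.approx(28.8, rel=0.03)

    def test_mistrust_mean(self):
        inst = {"mistrust": Instrument(20.5, 6.3, 10, 40)}
        scores = sample_questionnaires(inst, 10000, np.random.default_rng(16))
        assert scores["mistrust"].mean() == pytest.approx(20.5, abs=0.2)

    def test_zero_sd_gives_constant(self):
        inst = {"q": Instrument(12.3, 0.0, 0, 100)}
        scores = sample_questionnaires(inst, 50, np.random.default_rng(17))
        assert (scores["q"] == 12).all()

    def test_range_respected(self):
        # target SD infeasible for the range: falls back with a warning,
        # draws still clipped to the instrument range
        inst = {"q": Instrument(5.0, 30.0, 0, 20)}
        with pytest.warns(UserWarning, match="moment-match"):
            scores = sample_questionnaires(inst, 2000, np.random.default_rng(18))
        assert scores["q"].between(0, 20).all()


class TestCohortDeterminism:
    def test_glmm_cohort_reproducible(self):
        a = make_glmm_cohort(CohortConfig(n_subjects=10, seed=3), n_trials=20)
        b = make_glmm_cohort(CohortConfig(n_subjects=10, seed=3), n_trials=20)
        pd.testing.assert_frame_equal(a, b)

    def test_write_cohort_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_subjects=5, seed=4)
        df = make_glmm_cohort(cfg, n_trials=10)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(df, cfg, p1)
        write_cohort(df, cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()
        sidecar = p1.with_suffix(".config.json")
        assert sidecar.exists() and '"seed": 4' in sidecar.read_text()

    def test_trials_to_frame_roundtrip_columns(self, profile, rng):
        trials = [simulate_observer_trial(profile, 0.4, "explicit", rng)]
        df = trials_to_frame(trials)
        assert list(df.columns)[:7] == [
            "subject_id", "task", "coherence", "difficulty",
            "direction", "response", "correct",
        ]
        assert dataclasses.asdict(trials[0])["confidence"] == df["confidence"].iloc[0]
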