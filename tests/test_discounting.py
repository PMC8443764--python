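"""Choice-model tests: probability, likelihood, MLE, variants, r2, k-fold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tempodisc as td
from tempodisc.discounting import LOGK_BOUNDS, LOGTAU_BOUNDS, _neg_loglik


def make_choice_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "task", "sooner_reward", "later_reward",
                 "delay", "choice"],
    )


class TestChoiceProbability:
    def test_indifference_point_is_exactly_half(self):
        # 10 / (1 + 0.05 * 30) = 4 = sooner, for any noise level
        for logtau in (-2.0, 0.0, 2.0):
            p = td.hyperbolic_choice_probability(4, 10, 30, np.log(0.05), logtau)
            assert p == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        p = td.hyperbolic_choice_probability(4, 10, 30, np.log(0.1), 0.0)
        # discounted value 2.5; sigma(-1.5)
        assert p == pytest.approx(1 / (1 + np.exp(1.5)), abs=1e-12)
        assert p == pytest.approx(0.18243, abs=1e-5)

    def test_noiseless_dominance_at_zero_delay(self):
        p = td.hyperbolic_choice_probability(4, 10, 0, -3.0, -40.0)
        assert p == pytest.approx(1.0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            td.hyperbolic_choice_probability(4, 10, np.nan, -3.0, 0.0)
        with pytest.raises(ValueError):
            td.hyperbolic_choice_probability(4, 10, 30, np.inf, 0.0)

    @given(
        d1=st.floats(0.0, 200.0), d2=st.floats(0.0, 200.0),
        logk=st.floats(-8.0, 1.0), logtau=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_probability_decreasing_in_delay(self, d1, d2, logk, logtau):
        lo, hi = sorted((d1, d2))
        p_lo = td.hyperbolic_choice_probability(4, 10, lo, logk, logtau)
        p_hi = td.hyperbolic_choice_probability(4, 10, hi, logk, logtau)
        assert p_hi <= p_lo + 1e-12


class TestDatasetLogLikelihood:
    def params(self, logk=-3.0, logtau=0.0):
        return pd.DataFrame([
            {"subject_id": "a", "task": "SV", "logk": logk, "logtau": logtau},
        ])

    def test_half_probability_trials(self):
        # at the indifference point every trial contributes ln(1/2)
        rows = [("a", "SV", 4.0, 10.0, 30.0, c) for c in (0, 1, 1, 0, 1)]
        ll = td.dataset_log_likelihood(
            make_choice_frame(rows), self.params(logk=np.log(0.05))
        )
        assert ll == pytest.approx(5 * np.log(0.5))

    def test_single_trial_hand_value(self):
        rows = [("a", "SV", 4.0, 10.0, 30.0, 1)]
        ll = td.dataset_log_likelihood(
            make_choice_frame(rows), self.params(logk=np.log(0.1))
        )
        assert ll == pytest.approx(-1.7014, abs=1e-4)

    def test_vectorized_matches_per_trial_loop(self, small_dataset):
        trials = small_dataset["choices"]
        params = pd.DataFrame([
            {"subject_id": p.subject_id, "task": task,
             "logk": p.true_logk_sv if task == "SV" else p.true_logk_lv,
             "logtau": p.true_logtau}
            for p in small_dataset["profiles"] for task in ("SV", "LV")
        ])
        ll_vec = td.dataset_log_likelihood(trials, params)
        lookup = params.set_index(["subject_id", "task"])
        ll_loop = 0.0
        for _, t in trials.iterrows():
            row = lookup.loc[(t["subject_id"], t["task"])]
            p = td.hyperbolic_choice_probability(
                t["sooner_reward"], t["later_reward"], t["delay"],
                row["logk"], row["logtau"],
            )
            ll_loop += np.log(p if t["choice"] == 1 else 1 - p)
        assert ll_vec == pytest.approx(ll_loop, abs=1e-10)

    def test_missing_subject_named_in_error(self):
        rows = [("ghost", "SV", 4.0, 10.0, 30.0, 1)]
        with pytest.raises(KeyError, match="ghost"):
            td.dataset_log_likelihood(make_choice_frame(rows), self.params())


class TestSubjectMLE:
    def test_noiseless_recovery(self):
        prof = td.SubjectProfile("a", np.log(0.08), -3, -40.0, 1, 1, 1, 1)
        cfg = td.SimulationConfig(n_subjects=1, reps_per_combo=8)
        sched = td.build_task_schedule(cfg, "SV")
        trials = td.simulate_choices([prof], sched, "SV", seed=5)
        fit = td.fit_subject_mle(trials)
        assert fit.logk == pytest.approx(np.log(0.08), abs=0.2)

    def test_always_sooner_flagged_delay_insensitive(self):
        rows = [("a", "SV", 4.0, r, d, 0)
                for d in (3, 7, 14, 30, 64) for r in (1, 2, 5, 8, 10)]
        fit = td.fit_subject_mle(make_choice_frame(rows))
        assert fit.delay_insensitive and fit.at_boundary
        assert fit.logk == LOGK_BOUNDS[1]

    def test_matches_grid_search_oracle(self, small_dataset):
        trials = small_dataset["choices"].query(
            "subject_id == 's1' and task == 'SV'"
        )
        fit = td.fit_subject_mle(trials)
        args = (
            trials["sooner_reward"].to_numpy(float),
            trials["later_reward"].to_numpy(float),
            trials["delay"].to_numpy(float),
            trials["choice"].to_numpy(float),
        )
        ks = np.linspace(*LOGK_BOUNDS, 200)
        ts = np.linspace(*LOGTAU_BOUNDS, 200)
        nll = np.array([[_neg_loglik((k, t), *args) for t in ts] for k in ks])
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        assert abs(fit.logk - ks[i]) <= np.diff(ks)[0] + 1e-9
        assert abs(fit.logtau - ts[j]) <= np.diff(ts)[0] + 1e-9


class TestSubjectiveVariants:
    def fits(self, alpha, beta, form="linear", task="estimation"):
        return pd.DataFrame([{
            "subject_id": "a", "source_task": task, "form": form,
            "alpha": alpha, "beta": beta,
        }])

    def base_trials(self):
        return make_choice_frame([
            ("a", "SV", 4.0, 10.0, 30.0, 1),
            ("a", "LV", 4.0, 10.0, 30.0, 0),
        ])

    def test_identity_linear_fit(self):
        out = td.build_subjective_delay_variant(
            self.base_trials(), self.fits(1.0, 1.0), "subjTel"
        )
        assert (out["delay_effective"] == out["delay"]).all()

    def test_scaling_applies_to_sv_only(self):
        out = td.build_subjective_delay_variant(
            self.base_trials(), self.fits(2.0, 1.0), "subjTel"
        )
        assert out.loc[out["task"] == "SV", "delay_effective"].iloc[0] == 60.0
        assert out.loc[out["task"] == "LV", "delay_effective"].iloc[0] == 30.0

    def test_power_transform_value(self):
        trials = make_choice_frame([("a", "SV", 4.0, 10.0, 64.0, 1)])
        out = td.build_subjective_delay_variant(
            trials, self.fits(1.0, 0.9, form="power"), "subjTep"
        )
        assert out["delay_effective"].iloc[0] == pytest.approx(64 ** 0.9)
        assert out["delay_effective"].iloc[0] == pytest.approx(42.224, abs=1e-3)

    def test_objective_variant_is_identity(self):
        out = td.build_subjective_delay_variant(self.base_trials(), None, "obj")
        assert (out["delay_effective"] == out["delay"]).all()

    def test_missing_fit_rejected(self):
        trials = make_choice_frame([("b", "SV", 4.0, 10.0, 30.0, 1)])
        with pytest.raises(KeyError, match="b"):
            td.build_subjective_delay_variant(trials, self.fits(1.0, 1.0), "subjTel")

    def test_identity_fit_reproduces_objective_likelihood(self, small_dataset):
        trials = small_dataset["choices"]
        ident = pd.DataFrame([
            {"subject_id": p.subject_id, "source_task": "estimation",
             "form": "linear", "alpha": 1.0, "beta": 1.0}
            for p in small_dataset["profiles"]
        ])
        params = pd.DataFrame([
            {"subject_id": p.subject_id, "task": task,
             "logk": -3.0, "logtau": 0.0}
            for p in small_dataset["profiles"] for task in ("SV", "LV")
        ])
        ll_obj = td.dataset_log_likelihood(
            td.build_subjective_delay_variant(trials, None, "obj"), params)
        ll_subj = td.dataset_log_likelihood(
            td.build_subjective_delay_variant(trials, ident, "subjTel"), params)
        assert ll_subj == pytest.approx(ll_obj, abs=1e-10)


class TestKfoldComparison:
    def test_k_below_two_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            td.compare_models_kfold({"obj": small_dataset["choices"]}, k=1)

    def test_identical_variants_tie(self, small_dataset):
        trials = td.build_subjective_delay_variant(
            small_dataset["choices"].query("task == 'SV'"), None, "obj")
        out = td.compare_models_kfold({"a": trials, "b": trials.copy()}, k=3, seed=0)
        assert out["delta_elpd_from_best"].max() == pytest.approx(0.0, abs=1e-9)

    def test_power_variant_wins_when_time_is_compressive(self):
        """With strongly nonlinear subjective time driving the choices, the
        power-based variant should usually beat the linear-based variant."""
        wins = 0
        n_rep = 12
        for rep in range(n_rep):
            cfg = td.SimulationConfig(
                n_subjects=6, reps_per_combo=8, beta=0.7, alpha_sd=0.1,
                weber_fraction=0.1, mean_logk_sv=-2.0, sd_logk=0.5,
                mean_logtau=-1.2, sd_logtau=0.1, seed=1000 + rep,
            )
            profs = td.sample_population(cfg)
            # choices generated in subjective time: effective delay = a * d^0.7
            sched = td.build_task_schedule(cfg, "SV")
            subj_sched = sched.copy()
            fits = pd.DataFrame([
                {"subject_id": p.subject_id, "source_task": "estimation",
                 "form": "power", "alpha": p.true_alpha_e, "beta": p.true_beta}
                for p in profs
            ])
            lin_fits = pd.DataFrame([
                {"subject_id": p.subject_id, "source_task": "estimation",
                 "form": "linear", "alpha": p.true_alpha_e, "beta": 1.0}
                for p in profs
            ])
            frames = []
            for p in profs:
                st_delay = p.true_alpha_e * sched["delay"] ** p.true_beta
                prob = td.hyperbolic_choice_probability(
                    sched["sooner_reward"], sched["later_reward"], st_delay,
                    p.true_logk_sv, p.true_logtau,
                )
                rng = np.random.default_rng(5000 + rep * 100 + int(p.subject_id[1:]))
                df = sched.copy()
                df.insert(0, "subject_id", p.subject_id)
                df["choice"] = (rng.random(len(sched)) < prob).astype(int)
                frames.append(df)
            trials = pd.concat(frames, ignore_index=True)
            variants = {
                "power": td.build_subjective_delay_variant(
                    trials, pd.concat([fits, lin_fits]), "subjTep"),
                "linear": td.build_subjective_delay_variant(
                    trials, pd.concat([fits, lin_fits]), "subjTel"),
            }
            out = td.compare_models_kfold(variants, k=4, seed=rep)
            if out.iloc[0]["variant"] == "power":
                wins += 1
        assert wins >= 0.8 * n_rep
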