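import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cse_multiverse as cm
from cse_multiverse.hypothesis_tests import TestResult, TestSpec

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


def _balanced_trials(n_participants, per_cell, rng, interaction_ms=0.0,
                     subject_sd=60.0, resid_sd=90.0):
    """Trial table straight from a known linear model (no diffusion layer)."""
    rows = []
    for pid in range(n_participants):
        u = rng.normal(0, subject_sd)
        for prev, xp in (("c", 0), ("i", 1)):
            for cur, xc in (("C", 0), ("I", 1)):
                mu = 600 + 70 * xc + 5 * xp + interaction_ms * xc * xp + u
                rts = rng.normal(mu, resid_sd, per_cell) / 1000.0
                rows.append(pd.DataFrame({
                    "participant_id": pid, "prev_congruency": prev,
                    "congruency": cur, "rt_s": rts, "correct": 1,
                    "is_contaminant": 0, "trial_index": np.arange(per_cell)}))
    return pd.concat(rows, ignore_index=True)


class TestExcludeErrors:
    def test_counts(self, small_trials):
        out = cm.exclude_errors(small_trials)
        assert len(out) == (small_trials["correct"] == 1).sum()
        assert (out["correct"] == 1).all()

    def test_all_correct_is_identity(self, rng):
        trials = _balanced_trials(3, 10, rng)
        assert cm.exclude_errors(trials).equals(trials)

    def test_results_invariant_to_error_trial_rts(self, small_trials):
        """Error-trial RTs can be arbitrary: every pathway drops them first."""
        perturbed = small_trials.copy()
        errs = perturbed["correct"] == 0
        assert errs.any()
        perturbed.loc[errs, "rt_s"] = 99.0
        results = []
        for table in (small_trials, perturbed):
            kept, _ = cm.apply_filter(cm.exclude_errors(table), cm.parse_filter("sd2"))
            results.append(cm.rm_anova_cse(kept))
        assert results[0].interaction_estimate == results[1].interaction_estimate
        assert results[0].interaction_p == results[1].interaction_p


class TestRmAnova:
    def test_equals_paired_t_on_cse_scores(self, rng):
        """2x2 within-design algebra: interaction F == squared paired t and
        the p values agree to 1e-10."""
        trials = _balanced_trials(16, 25, rng, interaction_ms=-15)
        res = cm.rm_anova_cse(trials)
        means = trials.groupby(["participant_id", "prev_congruency", "congruency"])
        m = means["rt_s"].mean().unstack(["prev_congruency", "congruency"])
        scores = (m[("i", "I")] - m[("i", "C")]) - (m[("c", "I")] - m[("c", "C")])
        t, p = stats.ttest_rel(scores, np.zeros(len(scores)))
        assert res.interaction_p == pytest.approx(p, abs=1e-10)
        assert res.interaction_estimate == pytest.approx(scores.mean() * 1000, abs=1e-9)

    def test_no_variability_means_no_rejection(self):
        # identical cell means per participant -> zero CSE contrast, F = 0
        rows = []
        for pid in range(6):
            for prev in "ci":
                for cur in "CI":
                    rows.append({"participant_id": pid, "prev_congruency": prev,
                                 "congruency": cur, "rt_s": 0.5 + 0.01 * pid,
                                 "correct": 1, "is_contaminant": 0, "trial_index": 0})
        res = cm.rm_anova_cse(pd.DataFrame(rows))
        assert res.decision == 0

    def test_directional_rule_rejects_positive_interaction(self, rng):
        trials = _balanced_trials(20, 30, rng, interaction_ms=+40)
        res = cm.rm_anova_cse(trials)
        assert res.interaction_estimate > 0
        assert res.interaction_p < 0.05
        assert res.decision == 0

    def test_incomplete_participants_dropped(self, rng):
        trials = _balanced_trials(6, 10, rng)
        trials = trials.loc[~((trials.participant_id == 0)
                              & (trials.prev_congruency == "c")
                              & (trials.congruency == "C"))]
        res = cm.rm_anova_cse(trials)
        assert res.n_participants == 5
        assert any("dropped" in n for n in res.notes)

    def test_too_few_participants_flagged(self, rng):
        res = cm.rm_anova_cse(_balanced_trials(1, 10, rng))
        assert not res.converged


class TestLmm:
    def test_lrt_nonnegative_and_aic_identity(self, rng):
        trials = _balanced_trials(20, 30, rng, interaction_ms=-20)
        res = cm.fit_lmm_cse(trials, cm.parse_test("lmm"))
        assert res.converged
        lrt_stat = stats.chi2.isf(res.lrt_p, df=1)
        assert lrt_stat >= 0
        assert res.delta_aic == pytest.approx(lrt_stat - 2.0, abs=1e-6)

    def test_recovers_known_interaction(self, rng):
        """Parameter-recovery oracle on a linear-model dataset."""
        trials = _balanced_trials(150, 50, rng, interaction_ms=-20.86)
        res = cm.fit_lmm_cse(trials, cm.parse_test("lmm_cx"))
        se = 2 * 90 / np.sqrt(150 * 50)  # contrast SE from the residual SD
        assert res.converged
        assert abs(res.interaction_estimate - (-20.86)) < 3 * se

    def test_log_fit_on_exp_data_matches_raw_fit(self, rng):
        """log-variant on exp-transformed inputs reproduces the raw fit."""
        trials = _balanced_trials(12, 25, rng, interaction_ms=-25)
        raw = cm.fit_lmm_cse(trials, cm.parse_test("lmm"))
        exp_trials = trials.assign(rt_s=np.exp(trials["rt_s"]))
        log = cm.fit_lmm_cse(exp_trials, cm.parse_test("loglmm"))
        # raw fit reports ms, log fit reports log-units (= seconds here)
        assert log.interaction_estimate * 1000 == pytest.approx(
            raw.interaction_estimate, rel=1e-3)
        assert log.lrt_p == pytest.approx(raw.lrt_p, rel=1e-3, abs=1e-12)

    def test_anova_spec_rejected(self, rng):
        with pytest.raises(ValueError):
            cm.fit_lmm_cse(_balanced_trials(3, 5, rng), TestSpec("rm_anova"))

    def test_empty_table_is_nonconverged_not_an_exception(self, rng):
        trials = _balanced_trials(3, 5, rng).iloc[0:0]
        res = cm.fit_lmm_cse(trials, cm.parse_test("lmm"))
        assert not res.converged


class TestDecide:
    def _base(self, **kw):
        defaults = dict(kind="lmm_simple", converged=True, interaction_estimate=-15.0,
                        interaction_p=0.01, lrt_p=0.01, delta_aic=5.0, delta_bic=7.0)
        defaults.update(kw)
        return TestResult(**defaults)

    def test_information_criterion_gate(self):
        r = self._base(delta_aic=1.5, delta_bic=3.0)
        assert cm.decide(r, TestSpec("lmm_simple")) == 0

    def test_direction_gate(self):
        r = self._base(delta_aic=5.0, interaction_estimate=+8.0)
        assert cm.decide(r, TestSpec("lmm_simple")) == 0

    def test_all_criteria_met(self):
        assert cm.decide(self._base(), TestSpec("lmm_simple")) == 1

    def test_bic_alone_suffices_for_evidence_gate(self):
        r = self._base(delta_aic=1.0, delta_bic=6.0)
        assert cm.decide(r, TestSpec("lmm_simple")) == 1

    def test_nonconverged_is_undefined(self):
        r = self._base(converged=False)
        with pytest.raises(ValueError):
            cm.decide(r, TestSpec("lmm_simple"))

    def test_anova_rule(self):
        r = TestResult(kind="rm_anova", converged=True,
                       interaction_estimate=-10.0, interaction_p=0.03)
        assert cm.decide(r, TestSpec("rm_anova")) == 1
        r.interaction_estimate = 10.0
        assert cm.decide(r, TestSpec("rm_anova")) == 0
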