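import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cse_multiverse as cm
from cse_multiverse.ezdiff import DiffusionParams, EZError

PARAM_SETS = [
    (0.2, 0.12, 0.25),
    (0.1, 0.08, 0.30),
    (0.35, 0.15, 0.20),
    (-0.15, 0.10, 0.30),
    (0.25, 0.11, 0.40),
]


class TestClosedForms:
    @pytest.mark.parametrize("v,a,ter", PARAM_SETS)
    def test_round_trip_identity(self, v, a, ter):
        """ez_inverse(ez_forward(theta)) == theta to 1e-8."""
        acc, mrt, vrt = cm.ez_forward(DiffusionParams(v, a, ter))
        rec = cm.ez_inverse(mrt, vrt, acc)
        assert rec.drift_v == pytest.approx(v, abs=1e-8)
        assert rec.boundary_a == pytest.approx(a, abs=1e-8)
        assert rec.ter == pytest.approx(ter, abs=1e-8)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(v=st.floats(0.05, 0.5), a=st.floats(0.06, 0.2), ter=st.floats(0.0, 0.5),
           sign=st.sampled_from([-1.0, 1.0]))
    def test_round_trip_identity_property(self, v, a, ter, sign):
        acc, mrt, vrt = cm.ez_forward(DiffusionParams(sign * v, a, ter))
        rec = cm.ez_inverse(mrt, vrt, acc)
        assert np.allclose([rec.drift_v, rec.boundary_a, rec.ter],
                           [sign * v, a, ter], atol=1e-8)

    def test_ter_shift_moves_only_the_mean(self):
        p0 = DiffusionParams(0.2, 0.12, 0.25)
        p1 = DiffusionParams(0.2, 0.12, 0.25 + 0.07)
        acc0, mrt0, vrt0 = cm.ez_forward(p0)
        acc1, mrt1, vrt1 = cm.ez_forward(p1)
        assert mrt1 - mrt0 == pytest.approx(0.07, abs=1e-12)
        assert acc1 == acc0 and vrt1 == vrt0

    def test_accuracy_increases_with_drift(self):
        accs = [cm.ez_forward(DiffusionParams(v, 0.12, 0.25))[0]
                for v in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(accs) > 0)

    def test_zero_drift_forward_errors(self):
        with pytest.raises(EZError):
            cm.ez_forward(DiffusionParams(0.0, 0.12, 0.25))

    def test_inverse_error_conditions(self):
        with pytest.raises(EZError, match="drift undefined"):
            cm.ez_inverse(0.5, 0.03, 0.5)
        with pytest.raises(EZError):
            cm.ez_inverse(0.5, 0.03, 1.0)
        with pytest.raises(EZError):
            cm.ez_inverse(0.5, 0.0, 0.9)

    def test_edge_correction(self):
        assert cm.edge_correct(1.0, 100) == 1 - 1 / 200
        assert cm.edge_correct(0.0, 100) == 1 / 200
        assert cm.edge_correct(0.93, 100) == 0.93


class TestSampler:
    def test_all_rts_exceed_nondecision_time(self):
        p = DiffusionParams(0.2, 0.12, 0.25)
        rt, _ = cm.sample_trials(p, 5000, seed=1)
        assert (rt > p.ter).all()

    def test_zero_drift_is_a_fair_coin(self):
        rt, correct = cm.sample_trials(DiffusionParams(0.0, 0.12, 0.2), 100_000, seed=2)
        assert abs(correct.mean() - 0.5) < 3 * 0.5 / np.sqrt(100_000)

    @pytest.mark.parametrize("v,a,ter", PARAM_SETS)
    def test_moments_match_closed_forms(self, v, a, ter):
        """Sampler vs EZ closed forms, 3 MC SEs at 1e5 trials."""
        n = 100_000
        p = DiffusionParams(v, a, ter)
        acc, mrt, vrt = cm.ez_forward(p)
        rt, correct = cm.sample_trials(p, n, seed=hash((v, a)) % 2**31)
        assert abs(correct.mean() - acc) < 3 * np.sqrt(acc * (1 - acc) / n)
        assert abs(rt.mean() - mrt) < 3 * rt.std(ddof=1) / np.sqrt(n)
        # SE of the sample variance from the empirical fourth moment
        # (first-passage RTs are heavy-tailed; the normal 2/n rule is too tight)
        centered = rt - rt.mean()
        se_var = np.sqrt((np.mean(centered**4) - rt.var(ddof=1) ** 2) / n)
        assert abs(rt.var(ddof=1) - vrt) < 3 * se_var

    def test_seed_reproducibility(self):
        p = DiffusionParams(0.2, 0.12, 0.25)
        a = cm.sample_trials(p, 100, seed=9)
        b = cm.sample_trials(p, 100, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestContaminants:
    def test_exact_count_per_cell(self, small_trials):
        counts = small_trials.groupby(
            ["participant_id", "prev_congruency", "congruency"])["is_contaminant"].sum()
        assert (counts == round(0.05 * 50)).all()

    def test_zero_rate_is_identity(self, small_trials):
        out = cm.inject_contaminants(small_trials, 0.0, 0.0, 3.09, seed=1)
        assert out.equals(small_trials)

    def test_uniform_range_and_mean(self, flanker_params):
        trials = cm.generate_dataset(flanker_params, 40, 100, master_seed=5,
                                     contaminant_rate=0.5)
        cont = trials.loc[trials.is_contaminant == 1, "rt_s"]
        n = len(cont)
        assert n == 40 * 4 * 50
        assert cont.max() <= 3.09 and cont.min() >= 0.0
        se = 3.09 / np.sqrt(12 * n)
        assert abs(cont.mean() - 3.09 / 2) < 3 * se
        # fair-coin correctness, independent of RT
        corr = trials.loc[trials.is_contaminant == 1, "correct"]
        assert abs(corr.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_non_contaminant_rows_unchanged(self, flanker_params):
        base = cm.generate_dataset(flanker_params, 6, 40, master_seed=8,
                                   contaminant_rate=0.0)
        out = cm.inject_contaminants(base, 0.1, 0.0, 3.09, seed=3)
        assert len(out) == len(base)
        clean = out.is_contaminant == 0
        assert out.loc[clean, "rt_s"].equals(base.loc[clean, "rt_s"])
        assert out.loc[clean, "correct"].equals(base.loc[clean, "correct"])

    def test_invalid_bounds_rejected(self, small_trials):
        with pytest.raises(ValueError):
            cm.inject_contaminants(small_trials, 0.05, 1.0, 0.5, seed=1)
        with pytest.raises(ValueError):
            cm.inject_contaminants(small_trials, 1.5, 0.0, 3.09, seed=1)
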