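import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import septikit as sk
from septikit.io import SeptikitError
from .conftest import brute_force_auc

score_groups = st.tuples(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
)


class TestEmpiricalAuc:
    @pytest.mark.parametrize("cases,controls,expected", [
        ([2, 3], [0, 1], 1.0),
        ([0, 1], [2, 3], 0.0),
        ([1, 2], [1, 3], 0.375),  # one tie (0.5) + one concordant of 4 pairs
    ])
    def test_known_instances(self, cases, controls, expected):
        assert sk.empirical_auc(cases, controls).auc == pytest.approx(expected)

    @given(score_groups)
    @settings(max_examples=200, deadline=None)
    def test_matches_pair_counting_oracle(self, groups):
        cases, controls = groups
        assert sk.mann_whitney_auc(cases, controls) == \
            pytest.approx(brute_force_auc(cases, controls), abs=1e-12)

    @given(score_groups)
    @settings(max_examples=100, deadline=None)
    def test_complement_identity(self, groups):
        cases, controls = groups
        a = sk.mann_whitney_auc(cases, controls)
        b = sk.mann_whitney_auc([-c for c in cases], [-k for k in controls])
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        cases, controls = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        a = sk.mann_whitney_auc(cases, controls)
        b = sk.mann_whitney_auc(np.exp(cases), np.exp(controls))
        assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 50).round(1)  # ties on purpose
        y = rng.random(50) < 0.4
        assert sk.auc_from_scores(scores, y) == \
            pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(SeptikitError):
            sk.empirical_auc([], [1.0])

    def test_curve_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        s = sk.empirical_auc(rng.normal(1, 1, 25), rng.normal(0, 1, 25))
        fpr, tpr = s.curve[:, 0], s.curve[:, 1]
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert tuple(s.curve[0]) == (0.0, 0.0) and tuple(s.curve[-1]) == (1.0, 1.0)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        c, k = rng.normal(1, 1, 40), rng.normal(0, 1, 40)
        a = sk.bootstrap_auc_ci(c, k, reps=300, seed=5)
        b = sk.bootstrap_auc_ci(c, k, reps=300, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_perfect_separation_ci(self):
        c = np.linspace(10, 12, 200)
        k = np.linspace(0, 2, 200)
        s = sk.bootstrap_auc_ci(c, k, reps=300, seed=1)
        assert s.ci_high == 1.0 and s.ci_low > 0.95

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ci_contains_point_estimate(self, seed):
        rng = np.random.default_rng(seed)
        c, k = rng.normal(0.7, 1, 35), rng.normal(0, 1, 45)
        s = sk.bootstrap_auc_ci(c, k, reps=2000, seed=seed)
        assert s.ci_low <= s.auc <= s.ci_high


class TestBinormal:
    def test_equal_moments_give_half(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        assert sk.binormal_auc(x, x.copy()).auc == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_one_sd_separation(self):
        # equal unit variances, mean difference 1 -> AUC = Phi(1/sqrt(2))
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 2000)
        c = (base - base.mean()) / base.std(ddof=1) + 1.0
        k = (base - base.mean()) / base.std(ddof=1)
        assert sk.binormal_auc(c, k).auc == pytest.approx(sps.norm.cdf(1 / np.sqrt(2)),
                                                          abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        c, k = rng.normal(1, 1.4, 60), rng.normal(0, 0.8, 60)
        assert sk.binormal_auc(10 * c + 3, 10 * k + 3).auc == \
            pytest.approx(sk.binormal_auc(c, k).auc, abs=1e-12)

    def test_zero_variance_advises_empirical(self):
        with pytest.raises(SeptikitError, match="empirical"):
            sk.binormal_auc([1.0, 1.0], [0.0, 0.5])


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 40)
        y = np.arange(40) < 15
        res = sk.delong_test(s, s, y, paired=True)
        assert res.p_value == 1.0 and res.estimate == 0.0

    def test_variance_positive_for_distinct_inputs(self):
        rng = np.random.default_rng(6)
        y = np.arange(60) < 25
        a = rng.normal(0, 1, 60) + 0.8 * y
        b = rng.normal(0, 1, 60) + 0.4 * y
        res = sk.delong_test(a, b, y, paired=True)
        assert res.details["var_delta"] > 0

    def test_variance_close_to_jackknife(self):
        """DeLong variance of the AUC difference tracks the delete-one jackknife."""
        rng = np.random.default_rng(8)
        n1 = n0 = 50
        y = np.arange(n1 + n0) < n1
        a = rng.normal(0, 1, n1 + n0) + 1.0 * y
        b = rng.normal(0, 1, n1 + n0) + 0.5 * y

        def delta(mask):
            return (sk.auc_from_scores(a[mask], y[mask])
                    - sk.auc_from_scores(b[mask], y[mask]))

        full = np.ones(y.size, bool)
        loo = []
        for i in range(y.size):
            m = full.copy(); m[i] = False
            loo.append(delta(m))
        loo = np.asarray(loo)
        jk = 0.0
        for cls in (y, ~y):
            vals = loo[cls]
            jk += (cls.sum() - 1) / cls.sum() * ((vals - vals.mean()) ** 2).sum()
        res = sk.delong_test(a, b, y, paired=True)
        assert res.details["var_delta"] == pytest.approx(jk, rel=0.10)

    def test_unpaired_requires_second_labels(self):
        rng = np.random.default_rng(7)
        y = np.arange(20) < 10
        with pytest.raises(SeptikitError, match="labels_b"):
            sk.delong_test(rng.normal(size=20), rng.normal(size=22), y, paired=False)

    def test_unpaired_comparison_runs(self):
        rng = np.random.default_rng(7)
        ya = np.arange(40) < 18
        yb = np.arange(50) < 22
        a = rng.normal(0, 1, 40) + 1.2 * ya
        b = rng.normal(0, 1, 50) + 1.2 * yb
        res = sk.delong_test(a, b, ya, labels_b=yb, paired=False)
        assert 0 <= res.p_value <= 1 and res.paired is False


class TestVenkatraman:
    def test_identical_scores(self):
        rng = np.random.default_rng(9)
        s = rng.normal(0, 1, 30)
        y = np.arange(30) < 12
        res = sk.venkatraman_test(s, s, y, reps=200, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        y = np.arange(40) < 20
        a, b = rng.normal(size=40), rng.normal(size=40)
        p1 = sk.venkatraman_test(a, b, y, reps=300, seed=4).p_value
        p2 = sk.venkatraman_test(a, b, y, reps=300, seed=4).p_value
        assert p1 == p2

    def test_detects_strong_curve_difference(self):
        rng = np.random.default_rng(11)
        y = np.arange(80) < 40
        a = rng.normal(0, 1, 80) + 2.0 * y
        b = rng.normal(0, 1, 80)
        res = sk.venkatraman_test(a, b, y, reps=500, seed=3)
        assert res.p_value < 0.01

    def test_unpaired_mode_runs(self):
        rng = np.random.default_rng(12)
        ya = np.arange(40) < 20
        a = rng.normal(0, 1, 40) + ya
        b = rng.normal(0, 1, 40) + ya
        res = sk.venkatraman_test(a, b, ya, labels_b=ya, reps=300, seed=1, paired=False)
        assert 0 < res.p_value <= 1
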