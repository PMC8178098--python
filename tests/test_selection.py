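import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.feature_selection import f_classif

from phasemark.datatypes import ExpressionMatrix
from phasemark.selection import (
    anova_f,
    anova_f_matrix,
    benjamini_hochberg,
    intersect_phases,
    select_per_phase,
)

from conftest import random_matrix


class TestAnovaF:
    def test_hand_computed_example(self):
        F, p = anova_f([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert F == pytest.approx(8.0)
        assert p == pytest.approx(float(sps.f.sf(8.0, 1, 2)))

    def test_equal_means_give_zero(self):
        F, _ = anova_f([np.array([1.0, 3.0]), np.array([2.0, 2.0])])
        assert F == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_groups_equal_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
        F, p = anova_f([a, b])
        t, pt = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_scipy_f_oneway(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 5), (1, 7), (0.5, 6)]]
        F, p = anova_f(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_cases(self):
        F, p = anova_f([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert np.isinf(F) and p == 0.0  # MSE = 0, MST > 0
        F, p = anova_f([np.array([1.0, 1.0]), np.array([1.0, 1.0])])
        assert np.isnan(F)  # undefined

    def test_preconditions(self):
        with pytest.raises(ValueError):
            anova_f([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            anova_f([np.array([1.0]), np.array([])])
        with pytest.raises(ValueError):
            anova_f([np.array([1.0]), np.array([2.0])])  # n <= N

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=6), rng.normal(2, 1, size=7)]
        F1, _ = anova_f(groups)
        F2, _ = anova_f([7.3 * g for g in groups])
        assert F1 == pytest.approx(F2)


class TestAnovaMatrix:
    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_scipy_and_sklearn_columnwise(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 30))
        labels = np.repeat([0, 1, 2, 3], 6)
        F, p = anova_f_matrix(X, labels)
        Fs, ps = f_classif(X, labels)
        np.testing.assert_allclose(F, Fs, rtol=1e-8)
        np.testing.assert_allclose(p, ps, rtol=1e-8)
        for j in (0, 13, 29):
            ref = sps.f_oneway(*(X[labels == g, j] for g in range(4)))
            assert F[j] == pytest.approx(ref.statistic)

    def test_degenerate_columns(self):
        labels = np.array([0, 0, 1, 1])
        X = np.column_stack(
            [
                [5.0, 5.0, 5.0, 5.0],  # constant -> undefined
                [1.0, 1.0, 2.0, 2.0],  # within-constant -> infinite F
                [1.0, 2.0, 1.5, 2.5],  # ordinary
            ]
        )
        F, p = anova_f_matrix(X, labels)
        assert np.isnan(F[0]) and np.isnan(p[0])
        assert np.isinf(F[1]) and p[1] == 0.0
        assert np.isfinite(F[2])


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        q, reject = benjamini_hochberg(
            np.array([0.001, 0.008, 0.039, 0.041]), alpha=0.05
        )
        assert reject.all()  # k = 4 since 0.041 <= 4 * 0.05 / 4

    def test_all_ones(self):
        q, reject = benjamini_hochberg(np.ones(5), alpha=0.05)
        assert not reject.any() and (q == 1.0).all()

    @pytest.mark.parametrize("p,alpha", [(0.009, 0.01), (0.011, 0.01)])
    def test_single_p_reduces_to_raw_test(self, p, alpha):
        q, reject = benjamini_hochberg(np.array([p]), alpha=alpha)
        assert reject[0] == (p <= alpha)
        assert q[0] == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 11))
        p = np.round(rng.random(m), 3)
        alpha = 0.05
        _, reject = benjamini_hochberg(p, alpha)
        # oracle: evaluate every threshold k explicitly
        order = np.argsort(p)
        sorted_p = p[order]
        best_k = 0
        for k in range(1, m + 1):
            if sorted_p[k - 1] <= k * alpha / m:
                best_k = k
        expected = np.zeros(m, dtype=bool)
        expected[order[:best_k]] = True
        np.testing.assert_array_equal(reject, expected)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.2]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_step_up_property(self, p_list, alpha):
        """For any p-vector, BH rejections equal the exhaustive largest-k
        rule, and q-values are monotone in p with q >= p."""
        p = np.array(p_list)
        q, reject = benjamini_hochberg(p, alpha)
        m = p.size
        order = np.argsort(p, kind="stable")
        best_k = max(
            [0] + [k for k in range(1, m + 1) if p[order][k - 1] <= k * alpha / m]
        )
        assert reject.sum() == best_k
        if best_k:
            assert p[reject].max() <= p[order][best_k - 1]
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestSelection:
    def test_planted_markers_selected_with_low_false_discovery(self):
        rng = np.random.default_rng(0)
        n, P, n_markers = 24, 2000, 6
        labels = np.repeat([1, 2, 3, 4], 6)
        X = rng.normal(size=(n, P))
        for j in range(n_markers):  # 3 sigma group offsets
            X[:, j] += 3.0 * np.array([-1, 1, -1, 1])[labels - 1]
        em = ExpressionMatrix(
            [f"s{i}" for i in range(n)], [f"p{j}" for j in range(P)], X
        )
        sel = select_per_phase(em, labels, alpha=0.01)
        chosen = set(sel.significant)
        assert {f"p{j}" for j in range(n_markers)} <= chosen
        false_hits = len(chosen) - n_markers
        assert false_hits / max(len(chosen), 1) <= 0.2  # FDR controlled

    def test_single_group_labels_rejected(self):
        em = random_matrix(10, 5, 0)
        with pytest.raises(ValueError):
            select_per_phase(em, np.ones(10, dtype=int))

    def test_constant_probe_excluded_and_logged(self):
        em = random_matrix(12, 4, 1)
        em.values[:, 2] = 3.14
        sel = select_per_phase(em, np.repeat([1, 2, 3], 4), alpha=0.05)
        assert sel.excluded == ["p2"]
        assert "p2" not in sel.significant

    def test_intersection_semantics(self):
        from phasemark.selection import PhaseSelection
        import pandas as pd

        def mk(phase, sig):
            return PhaseSelection(phase, pd.DataFrame(), sig)

        res = intersect_phases(
            [mk("A", ["p2", "p1", "p3"]), mk("SA", ["p1", "p3"]), mk("C", ["p3", "p9"])]
        )
        assert res.final_set == ["p3"]
        res_empty = intersect_phases([mk("A", ["a"]), mk("SA", ["b"]), mk("C", ["c"])])
        assert res_empty.final_set == []
        with pytest.raises(ValueError):
            intersect_phases([mk("A", []), mk("SA", [])])

    def test_null_intersection_rate_far_below_alpha(self):
        """With no planted effects the three-phase intersection keeps
        essentially nothing: averaged over seeds the per-probe false
        selection rate is <= alpha."""
        labels = np.repeat([1, 2, 3, 4], 5)
        rates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sets = []
            for _ in range(3):
                X = rng.normal(size=(20, 400))
                F, p = anova_f_matrix(X, labels)
                _, rej = benjamini_hochberg(p, alpha=0.01)
                sets.append(set(np.flatnonzero(rej).tolist()))
            rates.append(len(sets[0] & sets[1] & sets[2]) / 400)
        assert np.mean(rates) <= 0.01
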