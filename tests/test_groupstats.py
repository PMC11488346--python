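"""Rank-sum tests, label-permutation association, BH, and correlations."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spatprox as sp

WINDOW = (500.0, 500.0)


def enumeration_mw_p(a, b):
    """Independent oracle: two-sided exact Mann–Whitney by enumerating every
    assignment of the pooled values to the two groups (tie-free inputs)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = (np.asarray(a)[:, None] > np.asarray(b)[None, :]).sum()
    center = n_a * len(b) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        g = pooled[list(idx)]
        r = np.delete(pooled, list(idx))
        u = (g[:, None] > r[None, :]).sum()
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = sp.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = sp.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and res.method == "exact"

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 3), (4, 2), (5, 5), (6, 6)])
    def test_exact_path_matches_enumeration_oracle(self, rng, n_a, n_b):
        for _ in range(5):
            pooled = rng.choice(1000, size=n_a + n_b, replace=False).astype(float)
            a, b = pooled[:n_a], pooled[n_a:]
            res = sp.mann_whitney_u(a, b)
            assert res.p_value == pytest.approx(enumeration_mw_p(a, b))
            # and agrees with the reference exact implementation (tie-free)
            ref = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert res.p_value == pytest.approx(float(ref))

    def test_large_samples_use_approximation(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = sp.mann_whitney_u(a, b)
        assert res.method == "approximate"
        ref = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(float(ref))

    def test_missing_values_excluded_and_counted(self):
        res = sp.mann_whitney_u([1, 2, np.nan], [4, np.nan, 6])
        assert res.n == (2, 2) and res.extra["n_excluded"] == 2

    def test_all_missing_group_undefined(self):
        with pytest.raises(sp.UndefinedTestError):
            sp.mann_whitney_u([np.nan, np.nan], [1, 2])

    def test_null_p_values_roughly_uniform(self, rng):
        # type-I calibration of the approximate path
        ps = [sp.mann_whitney_u(rng.normal(size=25),
                                rng.normal(size=25)).p_value
              for _ in range(300)]
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert rate == pytest.approx(0.05, abs=0.035)


class TestPermutationAssociation:
    def csr_table(self, seed):
        cfg = sp.TissueSimConfig(seed=seed, window=WINDOW, boundary="torus",
                                 background_intensities={"A": 1e-3, "B": 1e-3})
        return sp.simulate_csr(cfg)

    def query(self):
        return sp.ProximityQuery("A", "B", 20.0, boundary="torus", window=WINDOW)

    def test_zero_permutations_give_p_one(self):
        res = sp.permutation_association(self.csr_table(0), self.query(),
                                         n_perm=0, seed=1)
        assert res.p_value == 1.0

    def test_deterministic_under_seed(self):
        t = self.csr_table(3)
        a = sp.permutation_association(t, self.query(), n_perm=99, seed=7)
        b = sp.permutation_association(t, self.query(), n_perm=99, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_strong_attraction_detected(self, seed):
        # offspring clustered around parents on top of a diffuse background;
        # the diffuse component keeps the shuffled-label null close to CSR
        spec = sp.AttractionSpec("A", "B", parent_intensity=2e-4,
                                 mean_offspring=6.0, dispersion=5.0,
                                 offspring_background=3e-4)
        cfg = sp.TissueSimConfig(seed=seed, window=(1000.0, 1000.0),
                                 boundary="torus", attraction=spec)
        t = sp.simulate_attraction(cfg)
        q = sp.ProximityQuery("A", "B", 20.0, boundary="torus",
                              window=(1000.0, 1000.0))
        res = sp.permutation_association(t, q, n_perm=199, seed=0)
        assert res.p_value <= 0.01

    def test_missing_phenotype_undefined(self):
        cfg = sp.TissueSimConfig(seed=0, window=WINDOW, boundary="torus",
                                 background_intensities={"A": 1e-3})
        with pytest.raises(sp.UndefinedTestError):
            sp.permutation_association(sp.simulate_csr(cfg), self.query())

    def test_valid_under_label_exchangeable_null(self):
        # P(p <= alpha) <= alpha + Monte-Carlo tolerance on CSR tables
        ps = [sp.permutation_association(self.csr_table(s), self.query(),
                                         n_perm=99, seed=s).p_value
              for s in range(80)]
        alpha = 0.10
        rate = np.mean(np.asarray(ps) <= alpha)
        tol = 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
        assert rate <= alpha + tol


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert sp.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(sp.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = sp.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCorrelation:
    def test_monotone_pairs(self):
        rho, res = sp.correlate_infiltrates([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = [1.0, 4.0, 2.0, 8.0]
        rho, _ = sp.correlate_infiltrates(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        with pytest.raises(sp.UndefinedTestError):
            sp.correlate_infiltrates([1, 1, 1], [1, 2, 3])

    def test_missing_pairs_dropped(self):
        rho, res = sp.correlate_infiltrates([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert res.n == (3,)

    def test_recovers_known_rank_correlation(self, rng):
        # bivariate normal with rho chosen so Spearman's rho is 0.5
        rho_pearson = 2 * np.sin(np.pi * 0.5 / 6)
        cov = [[1, rho_pearson], [rho_pearson, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        est, _ = sp.correlate_infiltrates(xy[:, 0], xy[:, 1])
        assert est == pytest.approx(0.5, abs=0.15)


class TestCohortContrast:
    def test_flags_true_interaction_only(self):
        spec = sp.AttractionSpec("P", "O", parent_intensity=3e-4,
                                 mean_offspring=6.0, dispersion=5.0,
                                 offspring_background=1e-4)
        base = dict(window=(600.0, 600.0), boundary="torus",
                    background_intensities={"C": 5e-4})
        pos = sp.TissueSimConfig(seed=0, attraction=spec, **base)
        neg_spec = sp.AttractionSpec("P", "O", parent_intensity=3e-4,
                                     mean_offspring=0.0, dispersion=5.0,
                                     offspring_background=1e-4)
        neg = sp.TissueSimConfig(seed=0, attraction=neg_spec, **base)
        cohort = sp.CohortSimConfig(n_pos=15, n_neg=15, seed=2026,
                                    config_pos=pos, config_neg=neg)
        tables, _ = sp.simulate_cohort(cohort)
        metrics = sp.cohort_metric_table(tables, ["P", "O", "C"], radius=20.0,
                                         boundary="torus", window=(600.0, 600.0))
        contrast = sp.proximity_contrast(metrics, "pos", "neg")
        sig = contrast[contrast["adjusted_p"] < 0.05]
        flagged = set(zip(sig["central"], sig["surrounding"]))
        assert ("P", "O") in flagged
        # pairs not involving the offspring phenotype are never true contrasts
        null_pairs = {("P", "C"), ("C", "P")}
        assert not (flagged & null_pairs)
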