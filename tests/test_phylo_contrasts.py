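import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weantime import (
    NewickParseError,
    PairingError,
    SimConfig,
    ValidationError,
    contrast_correlation,
    homoscedasticity_diagnostic,
    independent_contrasts,
    parse_newick,
    simulate_bm_trait,
    simulate_tree,
)


def yule(n_tips: int, seed: int):
    return simulate_tree(SimConfig(n_taxa=n_tips, seed=seed))


def bm_cov_matrix(tree) -> tuple[list[str], np.ndarray]:
    """Brownian covariance: C[i, j] = shared root-to-MRCA path length."""
    labels = tree.tip_labels
    depths = tree.tip_depths()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                C[i, j] = depths[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                C[i, j] = 0.5 * (depths[a] + depths[b] - d)
    return labels, C


def gls_correlation(tree, xvals: dict, yvals: dict) -> float:
    """Independent matrix oracle: ML correlation under Brownian covariance."""
    labels, C = bm_cov_matrix(tree)
    x = np.array([xvals[l] for l in labels])
    y = np.array([yvals[l] for l in labels])
    Ci = np.linalg.inv(C)
    one = np.ones(len(labels))
    mx = (one @ Ci @ x) / (one @ Ci @ one)
    my = (one @ Ci @ y) / (one @ Ci @ one)
    xc, yc = x - mx, y - my
    return float(xc @ Ci @ yc / math.sqrt((xc @ Ci @ xc) * (yc @ Ci @ yc)))


class TestNewick:
    def test_minimal_tree(self):
        tree = parse_newick("(A:1,B:1);")
        assert tree.n_tips == 2
        assert sorted(tree.tip_labels) == ["A", "B"]

    def test_round_trip_is_isomorphic(self):
        tree = yule(12, seed=3)
        back = parse_newick(tree.to_newick())
        assert sorted(back.tip_labels) == sorted(tree.tip_labels)
        d1, d2 = tree.tip_depths(), back.tip_depths()
        for label in d1:
            assert d1[label] == pytest.approx(d2[label], rel=1e-9)

    @pytest.mark.parametrize("bad", ["", "(A:1,B:1)", "((A:1,B:1);", "(A:1,,B:1));"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_simulated_chronogram_is_ultrametric(self):
        tree = yule(67, seed=1)
        depths = np.array(list(tree.tip_depths().values()))
        assert np.ptp(depths) < 1e-9 * depths.max()
        assert tree.is_ultrametric()


class TestContrasts:
    def test_cherry_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        cset = independent_contrasts(tree, {"A": 4.0, "B": 1.0})
        assert cset.n_contrasts == 1
        assert abs(cset.contrasts[0]) == pytest.approx(3.0 / math.sqrt(2.0))

    def test_identical_values_give_zero_contrasts(self):
        tree = yule(10, seed=2)
        cset = independent_contrasts(tree, {l: 7.7 for l in tree.tip_labels})
        np.testing.assert_allclose(cset.contrasts, 0.0, atol=1e-12)

    def test_missing_tip_value_names_tip(self):
        tree = parse_newick("(A:1,(B:0.5,C:0.5):0.5);")
        with pytest.raises(ValidationError, match="C"):
            independent_contrasts(tree, {"A": 1.0, "B": 2.0})

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 500))
    def test_count_is_tips_minus_one(self, n_tips, seed):
        tree = yule(n_tips, seed=seed)
        values = simulate_bm_trait(tree, 0.02, 0.0, seed=seed + 1)
        cset = independent_contrasts(tree, values)
        assert cset.n_contrasts == tree.n_tips - 1

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(4, 8), st.integers(0, 200))
    def test_through_origin_correlation_equals_gls_oracle(self, n_tips, seed):
        tree = yule(n_tips, seed=seed)
        x = simulate_bm_trait(tree, 0.05, 0.0, seed=seed + 1)
        y = simulate_bm_trait(tree, 0.05, 1.0, seed=seed + 2)
        ca = independent_contrasts(tree, x)
        cb = independent_contrasts(tree, y)
        r, F, p = contrast_correlation(ca, cb)
        assert r == pytest.approx(gls_correlation(tree, x, y), abs=1e-8)
        assert 0 <= p <= 1

    def test_branch_scaling_rescales_contrasts(self):
        tree = yule(12, seed=9)
        values = simulate_bm_trait(tree, 0.05, 0.0, seed=4)
        base = np.array(independent_contrasts(tree, values).contrasts)
        k = 4.0
        scaled = np.array(independent_contrasts(tree.scale_branches(k), values).contrasts)
        np.testing.assert_allclose(scaled, base / math.sqrt(k), rtol=1e-9)

    def test_polytomy_resolved_with_epsilon_branches(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        cset = independent_contrasts(tree, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert cset.n_contrasts == 3  # fully resolved: T - 1 contrasts


class TestContrastCorrelation:
    def test_identity_and_sign_flip(self):
        tree = yule(15, seed=6)
        values = simulate_bm_trait(tree, 0.05, 0.0, seed=5)
        a = independent_contrasts(tree, values)
        r, _, _ = contrast_correlation(a, a)
        assert r == pytest.approx(1.0)
        neg = type(a)(a.node_ids, tuple(-c for c in a.contrasts), a.expected_sd)
        r, _, _ = contrast_correlation(a, neg)
        assert r == pytest.approx(-1.0)

    def test_mismatched_sets_raise(self):
        t1, t2 = yule(8, seed=1), yule(9, seed=2)
        a = independent_contrasts(t1, simulate_bm_trait(t1, 0.05, 0.0, 1))
        b = independent_contrasts(t2, simulate_bm_trait(t2, 0.05, 0.0, 2))
        with pytest.raises(PairingError):
            contrast_correlation(a, b)

    def test_f_uses_n_minus_2_denominator_df(self):
        tree = yule(67, seed=3)
        x = simulate_bm_trait(tree, 0.05, 0.0, seed=1)
        y = {k: 0.8 * v for k, v in x.items()}
        a = independent_contrasts(tree, x)
        b = independent_contrasts(tree, y)
        assert a.n_contrasts == 66
        r, F, _ = contrast_correlation(a, b)
        # r = 1 exactly; F formula checked on a noisy pair instead
        z = simulate_bm_trait(tree, 0.05, 0.0, seed=2)
        noisy = {k: 0.8 * x[k] + 0.6 * z[k] for k in x}
        c = independent_contrasts(tree, noisy)
        r, F, _ = contrast_correlation(a, c)
        assert F == pytest.approx(r * r * (a.n_contrasts - 2) / (1 - r * r), rel=1e-9)

    def test_recovers_true_brownian_correlation(self, fixed_tree):
        """Mean contrast correlation across replicates ~ the generating rho."""
        rho = 0.8
        rs = []
        for seed in range(100):
            x = simulate_bm_trait(fixed_tree, 0.05, 0.0, seed=2 * seed)
            z = simulate_bm_trait(fixed_tree, 0.05, 0.0, seed=2 * seed + 1)
            y = {k: rho * x[k] + math.sqrt(1 - rho ** 2) * z[k] for k in x}
            a = independent_contrasts(fixed_tree, x)
            b = independent_contrasts(fixed_tree, y)
            rs.append(contrast_correlation(a, b)[0])
        mean_r = float(np.mean(rs))
        mc_err = float(np.std(rs) / math.sqrt(len(rs)))
        assert abs(mean_r - rho) < max(4 * mc_err, 0.02)


def test_brownian_contrasts_are_homoscedastic(fixed_tree):
    """|contrast| shows no trend in its standardizing SD for BM data."""
    for seed in (1, 2, 3):
        values = simulate_bm_trait(fixed_tree, 0.05, 0.0, seed=seed)
        cset = independent_contrasts(fixed_tree, values)
        _, p = homoscedasticity_diagnostic(cset)
        assert p > 0.01
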