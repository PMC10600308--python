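import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pasl
from pasl.containers import GenesetCollection
from pasl.inference import _fix_sign
from pasl.io import build_membership

from .conftest import make_expression


class TestStandardize:
    def test_two_point_column(self):
        X = make_expression([[1.0], [3.0]])
        Xz, params = pasl.standardize(X)
        np.testing.assert_allclose(Xz[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])
        assert params.mu[0] == 2.0
        np.testing.assert_allclose(params.sigma[0], np.sqrt(2.0))

    def test_constant_column_guard(self):
        X = make_expression([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        Xz, params = pasl.standardize(X)
        np.testing.assert_array_equal(Xz[:, 0], 0.0)
        assert params.sigma[0] == 1.0

    def test_reapplying_params_is_idempotent(self, random_expression):
        Xz, params = pasl.standardize(random_expression)
        np.testing.assert_array_equal(params.apply(random_expression.values), Xz)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pasl.standardize(make_expression([[1.0, 2.0]]))


class TestBoxCox:
    @pytest.mark.parametrize(
        "y,lam,expected",
        [
            (1.0, 0.5, 0.0),
            (8.0, 0.0, np.log(8.0)),
            (27.0, 1.0 / 3.0, 6.0),
        ],
    )
    def test_known_values(self, y, lam, expected):
        assert pasl.box_cox(y, lam) == pytest.approx(expected)

    def test_continuous_at_lam_zero(self):
        for y in (2.0, 10.0, 500.0):
            assert pasl.box_cox(y, 1e-9) == pytest.approx(np.log(y), rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pasl.box_cox(0.0, 0.5)


class TestNormalizeVariance:
    def test_reference_value(self):
        assert pasl.normalize_variance(6.0, 27, 1.0 / 3.0) == pytest.approx(1.0)

    def test_smaller_geneset_scores_higher_for_equal_variance(self):
        small = pasl.normalize_variance(10.0, 30, 1.0 / 3.0)
        large = pasl.normalize_variance(10.0, 200, 1.0 / 3.0)
        assert small > large

    def test_lam_one_divides_by_size_minus_one(self):
        assert pasl.normalize_variance(58.0, 30, 1.0) == pytest.approx(2.0)

    def test_disabled_normalization_returns_raw(self):
        assert pasl.normalize_variance(7.5, 200, None) == 7.5


class TestGenesetPcaSpectrum:
    def test_full_support_equals_global_pca(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        spectrum = pasl.geneset_pca_spectrum(Xz, np.arange(Xz.shape[1]))
        svals = np.linalg.svd(Xz, compute_uv=False)
        np.testing.assert_allclose(
            [v for _, v in spectrum], svals**2, rtol=1e-10, atol=1e-8
        )

    def test_single_feature_variance_is_column_sum_of_squares(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        ((vec, var),) = pasl.geneset_pca_spectrum(Xz, np.array([3]))
        assert var == pytest.approx(float(np.sum(Xz[:, 3] ** 2)))
        assert abs(vec[0]) == pytest.approx(1.0)

    def test_rank_one_data_has_single_nonzero_variance(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        Xz = np.outer(u, v)
        spectrum = pasl.geneset_pca_spectrum(Xz, np.arange(6))
        variances = np.array([var for _, var in spectrum])
        assert variances[0] > 0
        np.testing.assert_allclose(variances[1:], 0, atol=1e-10 * variances[0])

    def test_first_mode_matches_head_of_full(self, random_expression, rng):
        Xz, _ = pasl.standardize(random_expression)
        g = np.sort(rng.choice(Xz.shape[1], size=7, replace=False))
        full = pasl.geneset_pca_spectrum(Xz, g, mode="full")
        first = pasl.geneset_pca_spectrum(Xz, g, mode="first")
        assert len(first) == 1
        np.testing.assert_allclose(first[0][1], full[0][1])
        np.testing.assert_allclose(first[0][0], full[0][0])

    def test_empty_support_rejected(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        with pytest.raises(ValueError):
            pasl.geneset_pca_spectrum(Xz, np.array([], dtype=int))


def _brute_force_order(Xz, G, a1, lam):
    """Independent oracle: pool every (geneset, component) pair and sort."""
    pool = []
    for i in range(G.m):
        g = G.support(i)
        svals = np.linalg.svd(Xz[:, g], compute_uv=False)
        total = float(np.sum(svals**2))
        for j, s in enumerate(svals):
            v = float(s**2)
            if v < 1e-10 * total:
                continue
            divisor = pasl.box_cox(float(len(g)), lam) if lam is not None else 1.0
            pool.append((v / divisor, i, j))
    pool.sort(key=lambda r: (-r[0], r[1], r[2]))
    return pool[:a1]


class TestOrderOfGenesets:
    @pytest.fixture
    def toy(self, rng):
        X = make_expression(rng.normal(size=(4, 7)))
        coll = GenesetCollection(
            [
                ("g1", "", frozenset({"f0", "f1", "f2"})),
                ("g2", "", frozenset({"f2", "f3", "f4"})),
                ("g3", "", frozenset({"f4", "f5", "f6"})),
            ]
        )
        G = build_membership(coll, X.feature_ids)
        Xz, _ = pasl.standardize(X)
        return Xz, G

    def test_top5_matches_brute_force_pooled_sort(self, toy):
        Xz, G = toy
        ledger = pasl.order_of_genesets(Xz, G, 5, 1.0 / 3.0)
        oracle = _brute_force_order(Xz, G, 5, 1.0 / 3.0)
        assert ledger.order == [i for _, i, _ in oracle]
        np.testing.assert_allclose(ledger.expected, [v for v, _, _ in oracle])
        assert len(ledger.order) == 5

    def test_repeats_allowed_and_expected_sorted(self, toy):
        Xz, G = toy
        ledger = pasl.order_of_genesets(Xz, G, 5, 1.0 / 3.0)
        assert np.all(np.diff(ledger.expected) <= 1e-12)

    def test_a1_one_returns_single_best_pair(self, toy):
        Xz, G = toy
        ledger = pasl.order_of_genesets(Xz, G, 1, 1.0 / 3.0)
        oracle = _brute_force_order(Xz, G, 1, 1.0 / 3.0)
        assert ledger.order == [oracle[0][1]]
        assert ledger.component == [oracle[0][2]]

    def test_identical_genesets_tie_broken_by_lower_index(self, rng):
        X = make_expression(rng.normal(size=(4, 7)))
        members = frozenset({"f1", "f2", "f3"})
        coll = GenesetCollection([("first", "", members), ("twin", "", members)])
        G = build_membership(coll, X.feature_ids)
        Xz, _ = pasl.standardize(X)
        ledger = pasl.order_of_genesets(Xz, G, 2, 1.0 / 3.0)
        assert ledger.order == [0, 1]
        assert ledger.expected[0] == pytest.approx(ledger.expected[1])

    def test_requesting_more_than_available_warns(self, toy):
        Xz, G = toy
        with pytest.warns(UserWarning, match="available"):
            ledger = pasl.order_of_genesets(Xz, G, 50, 1.0 / 3.0)
        assert len(ledger.order) < 50


class TestConstructAtomAndDeflate:
    def test_variance_concentrated_in_one_feature_yields_indicator(self):
        Xz = np.zeros((6, 5))
        Xz[:, 2] = np.array([3.0, -1.0, 2.0, -2.0, 1.0, -3.0])
        Xz[:, 0] = 1e-8 * np.arange(6)
        atom = pasl.construct_atom(Xz, np.array([0, 2, 4]))
        expected = np.zeros(5)
        expected[2] = 1.0
        np.testing.assert_allclose(atom.coeffs, expected, atol=1e-6)

    def test_support_and_unit_norm_contract(self, random_expression, rng):
        Xz, _ = pasl.standardize(random_expression)
        g = np.sort(rng.choice(Xz.shape[1], size=9, replace=False))
        atom = pasl.construct_atom(Xz, g)
        assert np.linalg.norm(atom.coeffs) == pytest.approx(1.0)
        outside = np.setdiff1d(np.arange(Xz.shape[1]), g)
        np.testing.assert_array_equal(atom.coeffs[outside], 0.0)

    def test_full_support_gives_leading_principal_component(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        atom = pasl.construct_atom(Xz, np.arange(Xz.shape[1]))
        _, s, vt = np.linalg.svd(Xz, full_matrices=False)
        np.testing.assert_allclose(np.abs(atom.coeffs), np.abs(vt[0]), atol=1e-8)
        assert atom.variance_removed == pytest.approx(s[0] ** 2)

    def test_fully_deflated_geneset_is_rejected(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        g = np.array([0, 1, 2])
        R = Xz.copy()
        R[:, g] = 0.0
        assert pasl.construct_atom(R, g) is None

    def test_deflate_makes_residual_orthogonal_to_atom(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        atom = pasl.construct_atom(Xz, np.arange(10))
        R = pasl.deflate(Xz, atom.coeffs)
        np.testing.assert_allclose(R @ atom.coeffs, 0.0, atol=1e-10)

    def test_deflation_is_idempotent(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        atom = pasl.construct_atom(Xz, np.arange(10))
        once = pasl.deflate(Xz, atom.coeffs)
        twice = pasl.deflate(once, atom.coeffs)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_orthogonal_direction_leaves_data_unchanged(self):
        Xz = np.zeros((4, 3))
        Xz[:, 0] = [1.0, -1.0, 2.0, -2.0]
        d = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(pasl.deflate(Xz, d), Xz)

    def test_non_unit_direction_rejected(self, random_expression):
        Xz, _ = pasl.standardize(random_expression)
        with pytest.raises(ValueError, match="unit norm"):
            pasl.deflate(Xz, np.ones(Xz.shape[1]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_frobenius_identity_on_random_matrices(self, seed):
        # ||deflated||_F^2 == ||X||_F^2 - ||X d||^2 for any unit d
        rng = np.random.default_rng(seed)
        Xz = rng.normal(size=(50, 200))
        d = rng.normal(size=200)
        d /= np.linalg.norm(d)
        R = pasl.deflate(Xz, d)
        lhs = np.sum(R**2)
        rhs = np.sum(Xz**2) - np.sum((Xz @ d) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-8)


class TestFixSign:
    def test_largest_coefficient_made_positive(self):
        v = np.array([0.1, -0.9, 0.2])
        np.testing.assert_array_equal(_fix_sign(v), -v)
        np.testing.assert_array_equal(_fix_sign(-v), -v)


class TestInferencePhase:
    def _fit_toy(self, rng, n_sets=3, t=0.9):
        X = make_expression(rng.normal(size=(20, 12)))
        entries = [
            (f"g{i}", "", frozenset({f"f{4 * i}", f"f{4 * i + 1}", f"f{4 * i + 2}"}))
            for i in range(n_sets)
        ]
        G = build_membership(GenesetCollection(entries), X.feature_ids)
        Xz, _ = pasl.standardize(X)
        return Xz, G

    def test_static_strategy_orders_only_once(self, rng):
        # overlapping genesets would trigger reorders at t>0, never at t=0
        X = make_expression(rng.normal(size=(20, 8)))
        entries = [
            ("a", "", frozenset({"f0", "f1", "f2", "f3"})),
            ("b", "", frozenset({"f2", "f3", "f4", "f5"})),
            ("c", "", frozenset({"f4", "f5", "f6", "f7"})),
        ]
        G = build_membership(GenesetCollection(entries), X.feature_ids)
        Xz, _ = pasl.standardize(X)
        _, ledger, _ = pasl.inference_phase(Xz, G, 6, t=0.0)
        assert ledger.reevaluations == 0

    def test_disjoint_genesets_static_equals_dynamic(self, rng):
        Xz, G = self._fit_toy(rng)
        atoms0, _, _ = pasl.inference_phase(Xz, G, 3, t=0.0)
        atoms1, _, _ = pasl.inference_phase(Xz, G, 3, t=1.0)
        assert [a.geneset_index for a in atoms0] == [a.geneset_index for a in atoms1]
        for a0, a1 in zip(atoms0, atoms1):
            np.testing.assert_allclose(a0.coeffs, a1.coeffs, atol=1e-10)

    def test_single_all_covering_geneset_reduces_to_pca(
        self, random_expression, all_covering_membership
    ):
        Xz, _ = pasl.standardize(random_expression)
        k = 5
        atoms, _, _ = pasl.inference_phase(Xz, all_covering_membership, k)
        svals = np.linalg.svd(Xz, compute_uv=False)
        np.testing.assert_allclose(
            [a.variance_removed for a in atoms], svals[:k] ** 2, rtol=1e-6
        )
        _, _, vt = np.linalg.svd(Xz, full_matrices=False)
        for a, v in zip(atoms, vt[:k]):
            assert abs(float(np.dot(a.coeffs, v))) == pytest.approx(1.0, abs=1e-6)

    def test_variance_ledger_conservation(self, rng):
        Xz, G = self._fit_toy(rng)
        atoms, _, R = pasl.inference_phase(Xz, G, 3)
        total = np.sum(Xz**2)
        removed = sum(a.variance_removed for a in atoms)
        assert np.sum(R**2) + removed == pytest.approx(total, rel=1e-6)

    def test_atom_support_within_its_geneset(self, rng):
        Xz, G = self._fit_toy(rng)
        atoms, _, _ = pasl.inference_phase(Xz, G, 3)
        for atom in atoms:
            support = set(np.flatnonzero(atom.coeffs))
            assert support <= set(G.support(atom.geneset_index))

    def test_dynamic_strategy_accepts_non_increasing_variances(self, rng):
        X = make_expression(rng.normal(size=(25, 10)))
        entries = [
            ("a", "", frozenset({"f0", "f1", "f2", "f3", "f4"})),
            ("b", "", frozenset({"f3", "f4", "f5", "f6"})),
            ("c", "", frozenset({"f6", "f7", "f8", "f9"})),
        ]
        G = build_membership(GenesetCollection(entries), X.feature_ids)
        Xz, _ = pasl.standardize(X)
        _, ledger, _ = pasl.inference_phase(Xz, G, 6, t=1.0)
        # the dynamic greedy maximizes the size-normalized variance, so that
        # is the sequence guaranteed to be non-increasing
        actuals = ledger.actual
        assert all(x >= y - 1e-9 for x, y in zip(actuals, actuals[1:]))

    def test_size_penalty_monotone_under_noise_padding(self, rng):
        # padding a geneset with pure-noise features must not raise its
        # normalized first-component variance (averaged over draws)
        lam = 1.0 / 3.0
        diffs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            factor = local.normal(size=(60, 1)) @ local.normal(size=(1, 10))
            noise = local.normal(size=(60, 20))
            Xz = np.hstack([factor + 0.3 * local.normal(size=(60, 10)), noise])
            Xz = Xz - Xz.mean(axis=0)
            small = pasl.geneset_pca_spectrum(Xz, np.arange(10), mode="first")[0][1]
            big = pasl.geneset_pca_spectrum(Xz, np.arange(20), mode="first")[0][1]
            diffs.append(
                pasl.normalize_variance(small, 10, lam)
                - pasl.normalize_variance(big, 20, lam)
            )
        assert np.mean(diffs) > 0
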